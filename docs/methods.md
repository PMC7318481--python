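# Methods

## The precursor grammar and its data

An MSDIN precursor is modelled as `leader + core + recognition` with leader
length 9–10 aa, core 6–11 aa and recognition 13–18 aa, total 31–38 aa. The
packaged curated collection (`src/msdin/data/precursors_*.tsv`) holds 110
transcriptome-derived rows and 70 rows cloned from genomic DNA across ten
*Amanita* species, two *Galerina* species and *Lepiota venenata*, each with
its printed segmentation, product label and, for cloned rows, GenBank
accession. One *G. sulciceps* row carries a premature stop in its core
(`I*GIGCNP`, a TGG→TGA mutation) and is handled as a pseudogene throughout.
The recognition minimum of 13 aa is set by the shortest curated recognition
(`CIDEDAEGATYLC`); all other rows have 14–18.

### Deduplication

`dedup_genes` collapses rows sharing (species, precursor amino-acid
string), preferring transcriptome-derived rows, and additionally merges a
cloned row onto a same-species row when both carry the same named toxin
product and their precursors differ by exactly one substitution confined to
the recognition segment. The second rule reflects how re-cloned copies of
named-toxin genes were treated in the original tables: such a pair is one
locus whose clone differs by allelic or amplification variation. Under
these rules the collection yields 151 nonrepetitive genes, 145 of them from
*Amanita*, with core-length histogram {6: 5, 7: 30, 8: 73, 9: 22, 10: 19,
11: 2} — matching the published tallies exactly.

### A census discrepancy, on purpose

The published census also reports 98 distinct encoded cyclopeptides (94
unnamed). The packaged tables contain 96 distinct non-pseudogene core
strings (92 unnamed) under *every* deduplication scheme — deduplication can
only lower the count, and 96 is the union over all 180 rows; including the
pseudogene core gives 97. The published figure cannot be derived from the
printed data (its own breakdown into species-unique and shared cores is
likewise off by the same margin), so `core_census` reports the honest 96/92
and `msdin reproduce` flags the two reference rows as mismatched rather
than silently adopting either number.

## Mining

Candidate ORFs come from a six-frame scan that reports **every**
Met-to-stop translation (nested Mets included) — a first-Met-only scan can
hide an embedded precursor behind an upstream ATG in flanking sequence.
Candidates of 30–40 aa are segmented by exhaustive enumeration of all
grammar-admissible splits; each split scores

    leader PSSM + recognition-start PSSM + recognition-end PSSM + b·[core ends in P]

in nats (log-odds). Components:

* **Leader PSSM** — 10 columns, right-anchored so the terminal leader
  residue always occupies column 10 (9-aa *Lepiota*-type leaders leave
  column 1 empty). Pseudocount 1; background = residue frequencies over all
  curated precursors, chosen so that composition-matched decoys score near
  zero.
* **Recognition-start PSSM** — 5 columns over the consensus C22-V23-G24-D25-D26.
* **Recognition-end PSSM** — 8 right-anchored columns over the conserved
  tail (..L31 T32 R33 G34 E35 · L37 C38). This term is identical for every
  candidate split of a given peptide, so it does not influence the chosen
  segmentation; it exists purely to separate genuine precursors from
  composition-matched decoys, which rarely imitate the leader and the
  recognition tail simultaneously.
* **Pro bonus** — b = 2 nats when the core ends in Pro (94.5% of curated
  cores do; exceptions such as GFLFWA exist, so the bonus is finite).

Ties break toward a Pro-terminal core, then the longer leader. Re-parsing
the curated precursors reproduces the printed segmentation for 146/151
(96.7%); the five failures are genuinely ambiguous splits (e.g. an 11-aa
core `IIIVLGLIIPL` against a 17-aa recognition starting `CVSD…`), and every
failure is logged with its best-scoring alternative.

The mining threshold is calibrated, not tuned: it is the minimum best-parse
score over the curated nonrepetitive precursors minus 1 nat (shipped as
`DEFAULT_THRESHOLD = 15.80`; regenerate with
`scripts/calibrate_threshold.py`). Pseudogene candidates — Met-initiated
translations with exactly one internal stop, 30–40 aa total — are gated on
the leader score alone (`DEFAULT_LEADER_THRESHOLD = 11.14`, calibrated the
same way), since a premature stop corrupts the downstream components.
Against 20,000 dipeptide-shuffled decoys the best decoy score is ≈13.5,
comfortably below threshold.

## Annotation

Toxin classes: exact core matches name the four known toxins
(α-amanitin IWGIGCNP, β-amanitin IWGIGCDP, phallacidin AWLVDCP, phalloidin
AWLATCP); a heptapeptide with Trp2/Cys6 is phallotoxin-like and an
octapeptide with Trp2/Cys6 amatoxin-like (both layouts can form the
tryptathionine Trp–Cys bridge); everything else is unknown. This rule
reproduces all 179 curated non-pseudogene product labels. Masses are of
the unmodified head-to-tail macrocycle (sum of monoisotopic residue
masses); amatoxin post-translational modifications — hydroxylations and
the tryptathionine bridge itself — are not modelled. No virotoxin class is
emitted (no encoding gene is known); a phallotoxin-like core one C→S
substitution from a virotoxin composition is only a remark in the class
definition, not a class.

## Conservation

Profiles use anchored consensus numbering: leader 1–10 right-anchored to
the leader end, core-terminal residue at 21, recognition start 22–26
left-anchored, recognition end 31–38 right-anchored; variable-length core
interiors and recognition middles are masked, and when a short recognition
makes the two anchor blocks overlap the left anchor wins. On the
145-sequence *Amanita* set the eight reported leader rates and the
core-terminal Pro rate reproduce exactly (e.g. M1 100% (145/145), S2 91.7%
(133/145), P21 94.5% (137/145)). The published recognition-anchor
numerators differ from any fixed anchoring of these data by 1–4 counts
(their logo padding is unspecified), so recognition positions are computed
under the documented anchoring and not asserted against the printed
figures.

The cross-genus α-amanitin comparison scores mean pairwise identity over
the shared anchored leader and recognition positions; on the curated set
*Galerina*↔*Lepiota* identity (0.52) exceeds *Amanita*↔*Galerina* (0.47)
and *Amanita*↔*Lepiota* (0.47) — the two later-acquiring genera are
mutually closer, consistent with a shared lateral origin of their
α-amanitin genes.

## In-silico PCR

Degenerate primers are matched per-base under IUPAC set membership (a
zero-mismatch match is exactly membership in the primer's expansion set);
the reverse primer is matched as its reverse complement downstream on the
forward strand, and every site pair whose product lies in 80–2000 nt is
reported. No annealing thermodynamics is modelled — match/mismatch is the
only criterion the cloning protocol specifies. The forward cloning primer
has degeneracy 512 and every expansion encodes the leader start MSDINAT.

## Gene structure

`spliced_align` assumes the CDS is an exact exon concatenation of the
genomic sequence (true for the cloned-gene use case and the generator) and
searches for a decomposition whose gaps all begin GT and end AG. The search
is a breadth-first walk over (CDS offset, genomic offset) states layered by
intron count, so the first solution found has the fewest introns, and
successor ordering makes boundary ties resolve to the leftmost donor —
deterministic output. Intron length ≥ 4 nt (the degenerate GT·AG minimum);
exons must be non-empty. A mismatch-tolerant mode is deliberately absent
from the default path.

The generator inserts GT..AG introns (default length 50–70 nt) at positions
keeping every exon ≥ 10 nt. The floor matters: unconstrained placement can
create micro-exons of 1–2 nt whose decomposition is inherently ambiguous
(a smaller intron count becomes available), which no aligner could — or
should — recover; real exons are never that short. Under these conditions
the round trip recovers 100% of intron counts and 100% of boundaries over
200 genes spanning 0–18 introns (covering 3-intron toxin genes through
18-intron POPA-type genes).

Translated search runs affine-gap local alignment (BLOSUM62, gap open 11,
extend 1 — BLAST protein conventions; a gap of length k costs 11 + k) on
all six translation frames via Biopython's PairwiseAligner; scores equal a
brute-force Gotoh dynamic program on random peptide pairs and are invariant
under reverse-complementing the target.

## Phylogenetics

Distances: p, JC69 (−¾ ln(1 − 4p/3)) and K80; saturated pairs raise an
error naming the pair rather than returning infinity. Neighbor joining is
the standard Saitou–Nei agglomeration with one numerical rule: a negative
branch length is clamped to zero and the deficit moved to the sister edge,
preserving the joined pair's path length. NJ recovers random additive
matrices (≤ 12 taxa) exactly — topology and path lengths — against a
brute-force path-length oracle, and agrees with scikit-bio's independent
implementation. Bootstrap resamples sites with replacement; replicate r
draws from a dedicated seeded stream, so supports are reproducible.
Likelihood models (HKY/GTR + I + Γ) and Bayesian inference are deliberately
out of scope: this is a desk-scale surrogate whose claims are about clade
structure, not support percentages on real accessions.

The HGT scenario models a duplicated POP locus on an 11-taxon species tree
(five *Amanita*, two *Galerina* + outgroup, two *Lepiota* + outgroup): the
POPA paralog evolves on the species tree while the POPB paralog evolves on
a tree in which the *Galerina* and *Lepiota* lineages were re-grafted next
to the *Amanita* clade with short stems — a lateral acquisition. Sequences
evolve under i.i.d. Jukes–Cantor sites (600 nt by default, branch lengths
0.02–0.25 substitutions/site chosen as ordinary fungal-gene divergences).
The diagnostic read-out mirrors the empirical incongruence: all toxin-taxon
POPB copies form one clade while POPA copies group by genus with their
outgroup neighbours. At the shipped seeds this holds in 95–100% of 20
replicates; across arbitrary seeds the success rate is ~85–100%, the
occasional failure being a weakly resolved POPA genus clade at 600 sites.

## What the synthetic data do and do not show

The generators sample leaders/recognitions per-column from curated residue
frequencies, core lengths from the curated histogram, and codons uniformly
over synonyms (no organism codon table is assumed); decoys are
dipeptide-shuffles of curated precursors so that the miner is calibrated
against composition-matched, locally realistic negatives. Passing these
benchmarks shows the pipeline inverts its own generative assumptions —
grammar-conformant genes in random contexts, exact exon concatenations,
i.i.d. JC sites. It does not demonstrate performance on real assemblies
(fragmented ORFs, sequencing error, biased codon usage, introns with
non-canonical splice sites), nor does the column-independent sampling
capture covariation between precursor positions.

## Problem sizes and defaults

| quantity | default | note |
|---|---|---|
| mining threshold | 15.80 nats | min curated parse score − 1 |
| leader threshold | 11.14 nats | pseudogene gate, same calibration |
| Pro-terminal core bonus | 2 nats | finite: non-Pro cores exist |
| PSSM pseudocount | 1 | additive per residue |
| miner benchmark | 20 genes + 200 decoys | |
| spliced-alignment benchmark | 200 genes, 0–18 introns | |
| intron length / min exon | 50–70 nt / 10 nt | |
| NJ benchmark | 100 additive matrices, ≤ 12 taxa | |
| HGT benchmark | 20 replicates × 600 sites | |
| amplicon size range | 80–2000 nt | |

These sizes keep the full suite and the reproduction script to a few
seconds while exercising every structure class (including the 19-exon
POPA-type gene).
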