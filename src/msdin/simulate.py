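"""Synthetic data generators.

These emulate the study conditions the pipeline was built for without any
downloads: MSDIN precursor ORFs hidden among decoy ORFs in random contigs
(standing in for assembled unigenes), GT..AG intron insertion for the
genomic-mode gene-structure tests, and Jukes-Cantor sequence evolution on
trees, including a paralog pair where one locus has undergone a horizontal
transfer (the POPA/POPB scenario).

Precursor sampling is anchored to the curated collection: leaders and
recognition anchors are drawn per column from the curated residue
frequencies, core lengths follow the curated length histogram
{6: 5, 7: 30, 8: 73, 9: 22, 10: 19, 11: 2} (normalised), and cores end in
Pro with probability 0.945.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from Bio.Data.CodonTable import standard_dna_table
from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import Seq

IUPAC_SETS = {c.upper(): set(b) for c, b in ambiguous_dna_values.items()}

from .records import FixtureRow, GeneModel, SequenceRecord

#: Core length distribution over lengths 6..11 (curated gene counts).
CORE_LENGTH_COUNTS = {6: 5, 7: 30, 8: 73, 9: 22, 10: 19, 11: 2}
CORE_TERMINAL_PRO_PROB = 0.945

_CODONS = {}
for codon, aa in standard_dna_table.forward_table.items():
    _CODONS.setdefault(aa, []).append(codon)
for aa in _CODONS:
    _CODONS[aa].sort()
STOP_CODONS = sorted(standard_dna_table.stop_codons)


@dataclass
class TreeSim:
    """Parameters for evolving an alignment on a tree.

    With ``hgt_clade`` set, a second locus is evolved on a copy of the tree
    in which that clade has been pruned and re-grafted as sister to the
    smallest clade containing ``hgt_dest`` (a horizontal transfer).
    """

    newick: str
    n_sites: int = 600
    hgt_clade: tuple[str, ...] = ()
    hgt_dest: tuple[str, ...] = ()
    hgt_stem_length: float = 0.03


@dataclass
class SimConfig:
    seed: int = 0
    n_precursors: int = 20
    n_decoy_orfs: int = 200
    contig_length_range: tuple[int, int] = (400, 1200)
    genomic_mode: bool = False
    n_introns_per_gene: int = 3
    intron_length_range: tuple[int, int] = (50, 70)
    core_length_counts: dict[int, int] = field(
        default_factory=lambda: dict(CORE_LENGTH_COUNTS))
    core_terminal_pro_prob: float = CORE_TERMINAL_PRO_PROB


def _column_freqs(seqs: Sequence[str], length: int, right_anchored: bool):
    cols = [Counter() for _ in range(length)]
    for s in seqs:
        offset = length - len(s) if right_anchored else 0
        for i, res in enumerate(s):
            j = offset + i
            if 0 <= j < length and res.isalpha():
                cols[j][res] += 1
    out = []
    for c in cols:
        residues = sorted(c)
        total = sum(c.values())
        out.append((residues, np.array([c[r] / total for r in residues])))
    return out


class PrecursorSampler:
    """Samples grammar-conformant precursors from curated residue statistics."""

    def __init__(self, fixtures: Sequence[FixtureRow], config: SimConfig | None = None):
        self.config = config or SimConfig()
        clean = [f for f in fixtures if not f.is_pseudogene]
        self._leader_cols = _column_freqs([f.leader for f in clean], 10, True)
        recogs = [f.recognition for f in clean]
        self._recog_start = _column_freqs([r[:5] for r in recogs], 5, False)
        self._recog_end = _column_freqs([r[-8:] for r in recogs], 8, False)
        middle = Counter()
        for r in recogs:
            middle.update(r[5:-8])
        self._middle = (sorted(middle), np.array(
            [middle[k] / sum(middle.values()) for k in sorted(middle)]))
        core_pool = Counter()
        for f in clean:
            core_pool.update(f.core[:-1])
        self._core_pool = (sorted(core_pool), np.array(
            [core_pool[k] / sum(core_pool.values()) for k in sorted(core_pool)]))
        self._recog_lengths = Counter(len(r) for r in recogs)

    def _draw(self, rng, residues_probs) -> str:
        residues, probs = residues_probs
        return residues[rng.choice(len(residues), p=probs)]

    def sample_precursor(self, rng) -> tuple[str, str, str]:
        leader = "".join(self._draw(rng, c) for c in self._leader_cols)
        lengths = sorted(self.config.core_length_counts)
        weights = np.array([self.config.core_length_counts[k] for k in lengths], float)
        clen = int(lengths[rng.choice(len(lengths), p=weights / weights.sum())])
        core = "".join(self._draw(rng, self._core_pool) for _ in range(clen - 1))
        core += "P" if rng.random() < self.config.core_terminal_pro_prob \
            else self._draw(rng, self._core_pool)
        # recognition length from the curated distribution, restricted so the
        # precursor stays within 31-38 aa
        lo = max(13, 31 - len(leader) - clen)
        hi = min(18, 38 - len(leader) - clen)
        rlens = [k for k in sorted(self._recog_lengths) if lo <= k <= hi]
        rw = np.array([self._recog_lengths[k] for k in rlens], float)
        rlen = int(rlens[rng.choice(len(rlens), p=rw / rw.sum())])
        recog = "".join(self._draw(rng, c) for c in self._recog_start)
        recog += "".join(self._draw(rng, self._middle) for _ in range(rlen - 13))
        recog += "".join(self._draw(rng, c) for c in self._recog_end)
        return leader, core, recog


def reverse_translate(peptide: str, rng) -> str:
    """CDS with uniformly random synonymous codons (no stop appended)."""
    return "".join(_CODONS[aa][rng.integers(len(_CODONS[aa]))] for aa in peptide)


def generate_precursor_gene(sampler: PrecursorSampler, rng
                            ) -> tuple[str, str, tuple[str, str, str]]:
    """One synthetic MSDIN gene: (precursor aa, cds, truth segmentation)."""
    leader, core, recog = sampler.sample_precursor(rng)
    precursor = leader + core + recog
    cds = reverse_translate(precursor, rng)
    return precursor, cds, (leader, core, recog)


def dipeptide_shuffle(seq: str, rng) -> str:
    """Permute non-overlapping dipeptide blocks (composition-matched decoy)."""
    blocks = [seq[i:i + 2] for i in range(0, len(seq), 2)]
    order = rng.permutation(len(blocks))
    return "".join(blocks[i] for i in order)


def _random_dna(rng, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


def embed_in_contigs(genes: Sequence[tuple[str, str, tuple[str, str, str]]],
                     fixtures: Sequence[FixtureRow], config: SimConfig,
                     rng) -> tuple[list[SequenceRecord], list[dict]]:
    """Place gene CDSs (plus stop) on random strands inside random contigs,
    and add decoy ORFs built from dipeptide-shuffled curated precursors.

    Returns (contigs, truth table); each truth row records the contig,
    strand, forward-strand coordinates and true segmentation of one gene.
    """
    contigs: list[SequenceRecord] = []
    truth: list[dict] = []
    lo, hi = config.contig_length_range
    clean = [f for f in fixtures if not f.is_pseudogene]
    for g, (precursor, cds, segs) in enumerate(genes):
        insert = cds + STOP_CODONS[rng.integers(len(STOP_CODONS))]
        length = int(rng.integers(lo, hi + 1))
        if length < len(insert) + 6:
            raise ValueError("contig shorter than insert")
        offset = int(rng.integers(3, length - len(insert) - 2))
        strand = "+" if rng.random() < 0.5 else "-"
        placed = insert if strand == "+" else str(Seq(insert).reverse_complement())
        seq = _random_dna(rng, offset) + placed + _random_dna(rng, length - offset - len(insert))
        cid = f"contig{g:04d}"
        contigs.append(SequenceRecord(id=cid, seq=seq))
        start = offset if strand == "+" else offset
        truth.append({
            "contig_id": cid, "strand": strand,
            "start": start, "end": start + len(insert),
            "precursor": precursor, "leader": segs[0], "core": segs[1],
            "recognition": segs[2],
        })
    for d in range(config.n_decoy_orfs):
        template = clean[rng.integers(len(clean))].precursor
        decoy_aa = "M" + dipeptide_shuffle(template[1:], rng)
        insert = reverse_translate(decoy_aa, rng) + STOP_CODONS[rng.integers(len(STOP_CODONS))]
        length = int(rng.integers(lo, hi + 1))
        offset = int(rng.integers(3, length - len(insert) - 2))
        strand = "+" if rng.random() < 0.5 else "-"
        placed = insert if strand == "+" else str(Seq(insert).reverse_complement())
        seq = _random_dna(rng, offset) + placed + _random_dna(rng, length - offset - len(insert))
        contigs.append(SequenceRecord(id=f"decoy{d:04d}", seq=seq))
    return contigs, truth


def insert_introns(cds: str, n: int, rng,
                   length_range: tuple[int, int] = (50, 70),
                   min_exon: int = 10,
                   gene_id: str = "gene") -> tuple[str, GeneModel]:
    """Insert n GT..AG introns at distinct interior CDS positions.

    Insertion points keep every exon at least ``min_exon`` nt long
    (micro-exons of a few bases would make the decomposition inherently
    ambiguous and do not occur in real genes). Returns the genomic sequence
    and the true GeneModel on it.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if n > 0 and len(cds) < (n + 1) * min_exon:
        raise ValueError(f"cannot place {n} introns in a {len(cds)} nt CDS")
    if n == 0:
        return cds, GeneModel(gene_id, [(0, len(cds))])
    # sample n insertion points with pairwise (and end) gaps >= min_exon by
    # distributing the slack among the n+1 exons
    slack = len(cds) - (n + 1) * min_exon
    cuts = np.sort(rng.integers(0, slack + 1, size=n))
    positions = [int(min_exon * (i + 1) + cuts[i]) for i in range(n)]
    lo, hi = length_range
    genomic_parts = []
    exons = []
    prev = 0
    goffset = 0
    for pos in positions:
        exon = cds[prev:pos]
        genomic_parts.append(exon)
        exons.append((goffset, goffset + len(exon)))
        goffset += len(exon)
        ilen = int(rng.integers(lo, hi + 1))
        intron = "GT" + _random_dna(rng, ilen - 4) + "AG"
        genomic_parts.append(intron)
        goffset += len(intron)
        prev = pos
    genomic_parts.append(cds[prev:])
    exons.append((goffset, goffset + len(cds) - prev))
    return "".join(genomic_parts), GeneModel(gene_id, exons)


def pcr_template(fwd, rev, rng, spacer: int = 200, flank: int = 60) -> SequenceRecord:
    """A template with one guaranteed binding site per primer.

    One concrete expansion of the forward primer and the reverse complement
    of one expansion of the reverse primer are planted around a random
    spacer, so a degenerate-primer search must report exactly one amplicon.
    """
    from .pcr import DegeneratePrimer

    fwd = fwd if isinstance(fwd, DegeneratePrimer) else DegeneratePrimer("fwd", fwd)
    rev = rev if isinstance(rev, DegeneratePrimer) else DegeneratePrimer("rev", rev)

    def pick(primer):
        return "".join(
            sorted(IUPAC_SETS[c])[rng.integers(len(IUPAC_SETS[c]))]
            for c in primer.iupac)

    fwd_site = pick(fwd)
    rev_site = str(Seq(pick(rev)).reverse_complement())
    seq = (_random_dna(rng, flank) + fwd_site + _random_dna(rng, spacer)
           + rev_site + _random_dna(rng, flank))
    return SequenceRecord(id="template", seq=seq)


def _parse_tree(newick: str):
    from skbio import TreeNode
    import io as _io
    return TreeNode.read(_io.StringIO(newick), format="newick")


def evolve_on_tree(tree, n_sites: int, rng) -> dict[str, str]:
    """i.i.d. Jukes-Cantor site evolution along a branch-length tree."""
    if n_sites < 1:
        raise ValueError("alignment length must be >= 1")
    root_states = rng.integers(0, 4, size=n_sites)
    seqs: dict[str, np.ndarray] = {}

    def descend(node, states):
        for child in node.children:
            b = child.length or 0.0
            p = 0.75 * (1 - np.exp(-4.0 * b / 3.0))
            mutate = rng.random(n_sites) < p
            new = states.copy()
            if mutate.any():
                shift = rng.integers(1, 4, size=int(mutate.sum()))
                new[mutate] = (new[mutate] + shift) % 4
            if child.is_tip():
                seqs[child.name] = new
            else:
                descend(child, new)

    tree_ = tree if hasattr(tree, "children") else _parse_tree(tree)
    descend(tree_, root_states)
    alphabet = np.array(list("ACGT"))
    return {k: "".join(alphabet[v]) for k, v in seqs.items()}


def _lca(tree, names: Sequence[str]):
    nodes = [tree.find(n) for n in names]
    return nodes[0] if len(nodes) == 1 else tree.lca(nodes)


def graft_clade(tree, clade: Sequence[str], dest: Sequence[str],
                stem_length: float = 0.03):
    """Copy of ``tree`` with ``clade`` pruned and re-grafted as sister to the
    smallest clade containing ``dest`` — a single horizontal-transfer event."""
    from skbio import TreeNode

    tree = _parse_tree(tree) if isinstance(tree, str) else tree.copy()
    donor = _lca(tree, clade)
    if {t.name for t in donor.tips()} != set(clade):
        raise ValueError("hgt_clade is not a clade of the tree")
    sub = donor.copy()
    sub.length = stem_length
    donor.parent.remove(donor)
    tree.prune()
    dest_node = _lca(tree, dest)
    holder = TreeNode(length=dest_node.length)
    grandparent = dest_node.parent
    grandparent.remove(dest_node)
    dest_node.length = stem_length
    holder.extend([dest_node, sub])
    grandparent.append(holder)
    return tree


def simulate_alignment_on_tree(tree_sim: TreeSim, rng) -> dict[str, dict[str, str]]:
    """Evolve one locus on the species tree and, when ``hgt_clade`` is set,
    a second locus on the transferred tree.

    Returns {"vertical": aln} and, for an HGT scenario, also "transferred".
    """
    species = _parse_tree(tree_sim.newick)
    out = {"vertical": evolve_on_tree(species, tree_sim.n_sites, rng)}
    if tree_sim.hgt_clade:
        hgt_tree = graft_clade(species, tree_sim.hgt_clade,
                               tree_sim.hgt_dest, tree_sim.hgt_stem_length)
        out["transferred"] = evolve_on_tree(hgt_tree, tree_sim.n_sites, rng)
    return out


#: A species tree for the POP paralog scenario: five toxin-producing Amanita,
#: two Galerina (sister to outgroup og1) and two Lepiota (sister to og2).
POP_SPECIES_NEWICK = (
    "((am1:0.06,(am2:0.05,(am3:0.04,(am4:0.03,am5:0.03):0.02):0.02):0.02):0.20,"
    "(((gal1:0.04,gal2:0.04):0.10,og1:0.16):0.06,"
    "((lep1:0.04,lep2:0.04):0.10,og2:0.16):0.06):0.05);"
)

AMANITA_TAXA = tuple(f"am{i}" for i in range(1, 6))
GALERINA_TAXA = ("gal1", "gal2")
LEPIOTA_TAXA = ("lep1", "lep2")
TOXIN_TAXA = AMANITA_TAXA + GALERINA_TAXA + LEPIOTA_TAXA


def pop_hgt_scenario(rng, n_sites: int = 600, paralog_stem: float = 0.25):
    """Combined POPA/POPB alignment under the horizontal-transfer hypothesis.

    One ancestral POP duplicates into a POPA paralog that follows the
    species tree and a POPB paralog whose Galerina and Lepiota lineages were
    acquired by transfer from the Amanita lineage, so all toxin-species POPB
    copies form one tight clade. Leaves are labelled ``<taxon>_POPA`` /
    ``<taxon>_POPB``; the outgroups carry a generic vertically-inherited POP
    on both sides.

    Returns (alignment, popa_labels, popb_toxin_labels).
    """
    from skbio import TreeNode

    species = _parse_tree(POP_SPECIES_NEWICK)
    hgt = graft_clade(species, GALERINA_TAXA, AMANITA_TAXA)
    hgt = graft_clade(hgt, LEPIOTA_TAXA, GALERINA_TAXA)
    popa, popb = species.copy(), hgt
    for tip in popa.tips():
        tip.name += "_POPA"
    for tip in popb.tips():
        tip.name += "_POPB"
    popa.length = popb.length = paralog_stem
    combined = TreeNode(children=[popa, popb])
    aln = evolve_on_tree(combined, n_sites, rng)
    popa_labels = {t + "_POPA" for t in TOXIN_TAXA + ("og1", "og2")}
    popb_toxin_labels = {t + "_POPB" for t in TOXIN_TAXA}
    return aln, popa_labels, popb_toxin_labels
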