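"""Gene structure: spliced CDS-to-genomic alignment and translated local search.

``spliced_align`` recovers exon/intron structure when the CDS is an exact
exon concatenation of the genomic sequence (the cloned-gene use case):
it searches for a decomposition genomic = exon1 + intron1 + ... + exonK
where every intron begins GT and ends AG, preferring the decomposition with
the fewest introns and, among those, the leftmost donor sites.

``translated_sw_search`` is a desk-scale stand-in for TBLASTN retrieval:
affine-gap Smith-Waterman of a protein query against all six translation
frames of nucleotide records.
"""

from __future__ import annotations

from collections import deque

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .records import GeneModel, LocalAlignment

GAP_OPEN = 11
GAP_EXTEND = 1


class SplicedAlignmentError(ValueError):
    """No exact GT..AG decomposition of the genomic sequence exists."""


def _common_prefix(a: str, b: str) -> int:
    n = min(len(a), len(b))
    i = 0
    while i < n and a[i] == b[i]:
        i += 1
    return i


def spliced_align(cds: str, genomic: str, gene_id: str = "gene",
                  min_intron: int = 4) -> GeneModel:
    """Exact spliced alignment of a CDS onto its genomic sequence.

    Breadth-first search over (cds offset, genomic offset) states layered by
    intron count, so the first complete decomposition found uses the fewest
    introns; successor ordering (donor position ascending) makes boundary
    ties resolve to the leftmost donor.
    """
    cds, genomic = cds.upper(), genomic.upper()
    if len(cds) > len(genomic):
        raise SplicedAlignmentError("CDS longer than genomic sequence")
    if len(cds) < 50:
        raise SplicedAlignmentError("sequences shorter than 50 nt")
    if cds == genomic:
        return GeneModel(gene_id, [(0, len(genomic))])

    nc, ng = len(cds), len(genomic)
    # acceptor candidates: positions e such that genomic[e-2:e] == "AG"
    acceptors = [e for e in range(2, ng + 1) if genomic[e - 2:e] == "AG"]

    start = (0, 0)
    parent: dict[tuple[int, int], tuple[tuple[int, int], tuple[int, int]]] = {}
    queue: deque[tuple[int, int]] = deque([start])
    seen = {start}
    while queue:
        ci, gi = queue.popleft()
        ext = _common_prefix(cds[ci:], genomic[gi:])
        if ci + ext == nc and gi + ext == ng:
            return _reconstruct(gene_id, (ci, gi), parent, nc, ng)
        # open an intron after t matched bases (exons must be non-empty)
        for t in range(1, ext + 1):
            donor = gi + t
            if genomic[donor:donor + 2] != "GT":
                continue
            nci = ci + t
            if nci >= nc:  # a trailing intron would leave an empty last exon
                continue
            for e in acceptors:
                if e - donor < min_intron:
                    continue
                if e > ng - (nc - nci):
                    break
                # the next exon must resume matching (or finish exactly)
                if nci < nc and (e >= ng or genomic[e] != cds[nci]):
                    continue
                state = (nci, e)
                if state in seen:
                    continue
                seen.add(state)
                parent[state] = ((ci, gi), (donor, e))
                queue.append(state)
    raise SplicedAlignmentError(
        f"{gene_id}: no exact GT..AG decomposition of the genomic sequence"
    )


def _reconstruct(gene_id, state, parent, nc, ng) -> GeneModel:
    introns = []
    while state in parent:
        state, intron = parent[state]
        introns.append(intron)
    introns.reverse()
    exons = []
    prev = 0
    for s, e in introns:
        exons.append((prev, s))
        prev = e
    exons.append((prev, ng))
    model = GeneModel(gene_id, exons)
    assert sum(e - s for s, e in exons) == nc
    return model


def extract_cds(model: GeneModel, genomic: str) -> str:
    return "".join(genomic[s:e] for s, e in model.exons)


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    # BLAST protein convention: a gap of length k costs open + k*extend
    aligner.open_gap_score = -(GAP_OPEN + GAP_EXTEND)
    aligner.extend_gap_score = -GAP_EXTEND
    return aligner


def local_align_score(query: str, target: str) -> float:
    """Affine-gap Smith-Waterman score (BLOSUM62, gap 11/1) of two peptides."""
    if not query or not target:
        raise ValueError("empty sequence")
    return float(_make_aligner().score(query, target))


def translated_sw_search(query: str, records, min_score: float = 50.0
                         ) -> list[LocalAlignment]:
    """Search a protein query against six-frame translations of dna records.

    Returns per-frame local alignments scoring >= min_score, best first.
    Scores are invariant under reverse-complementing a target.
    """
    if not query:
        raise ValueError("empty query")
    aligner = _make_aligner()
    hits: list[LocalAlignment] = []
    for rec in records:
        n = len(rec.seq)
        for strand, seq in (("+", rec.seq), ("-", str(Seq(rec.seq).reverse_complement()))):
            for frame in range(3):
                aa = str(Seq(seq[frame:frame + 3 * ((n - frame) // 3)]).translate())
                if not aa:
                    continue
                score = float(aligner.score(query, aa))
                if score >= min_score:
                    aln = max(aligner.align(query, aa), key=lambda a: a.score)
                    qspan = (int(aln.aligned[0][0][0]), int(aln.aligned[0][-1][1]))
                    tspan = (int(aln.aligned[1][0][0]), int(aln.aligned[1][-1][1]))
                    hits.append(LocalAlignment(
                        query_id="query", target_id=rec.id, score=score,
                        strand=strand, frame=frame,
                        query_span=qspan, target_span=tspan,
                    ))
    hits.sort(key=lambda h: (-h.score, h.target_id, h.strand, h.frame))
    return hits
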