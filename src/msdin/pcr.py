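"""In-silico degenerate-primer PCR.

Matching is exact per-base set membership under the IUPAC nucleotide codes;
no annealing thermodynamics is modelled. The forward primer must match the
forward strand and the reverse primer's reverse complement must match
downstream on the same strand; an amplicon is the inclusive span from the
forward primer's first base to the reverse primer's last.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import prod

from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import Seq

from .records import SequenceRecord

IUPAC = {code.upper(): set(bases) for code, bases in ambiguous_dna_values.items()}

#: Degenerate primers used to clone partial MSDIN genes from genomic DNA.
FORWARD_PRIMER = "ATGTCNGAYATYAAYGCNACNCG"
REVERSE_PRIMER = "CCAAGCCTRAYAWRGTCMACAAC"


@dataclass
class DegeneratePrimer:
    name: str
    iupac: str

    def __post_init__(self) -> None:
        bad = set(self.iupac) - set(IUPAC)
        if bad:
            raise ValueError(f"primer {self.name!r}: illegal IUPAC codes {sorted(bad)}")

    @property
    def degeneracy(self) -> int:
        return prod(len(IUPAC[c]) for c in self.iupac)

    def expansions(self, limit: int = 100_000):
        """All concrete sequences the primer represents."""
        if self.degeneracy > limit:
            raise ValueError(f"degeneracy {self.degeneracy} exceeds limit {limit}")
        for combo in itertools.product(*(sorted(IUPAC[c]) for c in self.iupac)):
            yield "".join(combo)


def primer_degeneracy(primer: str | DegeneratePrimer) -> int:
    if isinstance(primer, str):
        primer = DegeneratePrimer("primer", primer)
    return primer.degeneracy


def _matches_at(template: str, pos: int, iupac: str, max_mismatch: int) -> bool:
    if pos < 0 or pos + len(iupac) > len(template):
        return False
    mismatches = 0
    for code, base in zip(iupac, template[pos:pos + len(iupac)]):
        if base not in IUPAC[code]:
            mismatches += 1
            if mismatches > max_mismatch:
                return False
    return True


def _match_positions(template: str, iupac: str, max_mismatch: int) -> list[int]:
    return [
        i for i in range(len(template) - len(iupac) + 1)
        if _matches_at(template, i, iupac, max_mismatch)
    ]


@dataclass
class Amplicon:
    template_id: str
    start: int  # 0-based half-open span on the forward strand
    end: int
    seq: str

    @property
    def length(self) -> int:
        return self.end - self.start


def find_amplicons(template: SequenceRecord, fwd: str | DegeneratePrimer,
                   rev: str | DegeneratePrimer, max_mismatch: int = 0,
                   size_range: tuple[int, int] = (80, 2000)) -> list[Amplicon]:
    """All primer-pair products on a template within ``size_range``.

    Every (forward site, reverse site) pair yielding a product length inside
    the range is reported; primers must lie entirely within the template.
    """
    fwd_seq = fwd.iupac if isinstance(fwd, DegeneratePrimer) else fwd
    rev_seq = rev.iupac if isinstance(rev, DegeneratePrimer) else rev
    rev_rc = str(Seq(rev_seq).reverse_complement())
    seq = template.seq
    lo, hi = size_range
    out = []
    for f in _match_positions(seq, fwd_seq, max_mismatch):
        for r in _match_positions(seq, rev_rc, max_mismatch):
            end = r + len(rev_rc)
            size = end - f
            if r >= f and lo <= size <= hi:
                out.append(Amplicon(template.id, f, end, seq[f:end]))
    return out
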