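"""Anchored per-position residue conservation over precursor sets.

Positions follow the consensus numbering of a full-length 38-aa precursor:

* 1-10: leader, right-anchored to the leader end (position 10 is always the
  terminal leader residue, so 9-aa leaders leave position 1 empty);
* 21: the core-terminal residue (the second POPB cleavage site);
* 22-26: recognition start, left-anchored (consensus C22 V23 G24 D25 D26);
* 31-38: recognition end, right-anchored to 38.

Core interiors (positions 11-20) are undefined for variable-length cores and
are not profiled; recognition middles between the two anchors are masked.
When a short recognition makes the two anchor blocks overlap, the left
anchor wins.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

from .records import FixtureRow, PrecursorRecord

LEADER_POSITIONS = tuple(range(1, 11))
CORE_TERMINAL = 21
RECOG_START_POSITIONS = tuple(range(22, 27))
RECOG_END_POSITIONS = tuple(range(31, 39))
ALL_POSITIONS = LEADER_POSITIONS + (CORE_TERMINAL,) + RECOG_START_POSITIONS + RECOG_END_POSITIONS


@dataclass
class ConservationProfile:
    n: int
    positions: dict[int, Counter] = field(default_factory=dict)

    def occupancy(self, position: int) -> int:
        return sum(self.positions[position].values())


def _anchored_residues(row) -> dict[int, str]:
    out: dict[int, str] = {}
    leader, core, recog = row.leader, row.core, row.recognition
    for i, res in enumerate(leader):
        out[10 - len(leader) + 1 + i] = res
    out[CORE_TERMINAL] = core[-1]
    taken: set[int] = set()
    for i, res in enumerate(recog[:5]):
        out[22 + i] = res
        taken.add(i)
    tail = recog[-8:]
    for i, res in enumerate(tail):
        idx = len(recog) - 8 + i
        if idx in taken:  # left anchor wins on overlap
            continue
        out[31 + i] = res
    return out


def build_profile(rows: Sequence[FixtureRow | PrecursorRecord]) -> ConservationProfile:
    """Anchored residue counts over a parsed precursor set."""
    if not rows:
        raise ValueError("cannot profile an empty precursor set")
    profile = ConservationProfile(n=len(rows), positions={p: Counter() for p in ALL_POSITIONS})
    for row in rows:
        if not row.leader or not row.core or not row.recognition:
            raise ValueError(f"unparsed input row {getattr(row, 'gene_id', row)!r}")
        for pos, res in _anchored_residues(row).items():
            profile.positions[pos][res] += 1
    return profile


def conservation_rate(profile: ConservationProfile, position: int, residue: str
                      ) -> tuple[float, tuple[int, int]]:
    """Fraction and (count, n) of ``residue`` at an anchored ``position``.

    The denominator is the number of sequences occupying that position, so
    the pair mirrors the conventional "x% (k/n)" report style.
    """
    if position not in profile.positions:
        raise KeyError(f"position {position} is not an anchored position")
    n_occ = profile.occupancy(position)
    if n_occ == 0:
        raise ValueError(f"position {position} is unoccupied")
    count = profile.positions[position][residue]
    return count / n_occ, (count, n_occ)


def logo_matrix(profile: ConservationProfile) -> dict[int, dict[str, float]]:
    """Position x residue probability table for logo-style plotting."""
    out = {}
    for pos in ALL_POSITIONS:
        n_occ = profile.occupancy(pos)
        if n_occ:
            out[pos] = {res: c / n_occ for res, c in sorted(profile.positions[pos].items())}
    return out


def _anchored_identity(a, b) -> tuple[int, int]:
    ra, rb = _anchored_residues(a), _anchored_residues(b)
    shared = [p for p in ra if p in rb and p != CORE_TERMINAL]
    return sum(ra[p] == rb[p] for p in shared), len(shared)


def compare_alpha_amanitin_precursors(rows: Sequence[FixtureRow | PrecursorRecord]
                                      ) -> dict[tuple[str, str], float]:
    """Mean pairwise identity of alpha-amanitin precursors within/between genera.

    Identity is computed over the shared anchored leader and recognition
    positions (the hypervariable core interior carries no alignment signal
    across genera). Returns a symmetric genus-pair -> identity map.
    """
    by_genus: dict[str, list] = {}
    for r in rows:
        if r.core == "IWGIGCNP":
            by_genus.setdefault(r.genus, []).append(r)
    if len(by_genus) < 2:
        raise ValueError("need alpha-amanitin records from >= 2 genera")
    for genus, members in by_genus.items():
        if not members:
            raise ValueError(f"genus {genus} has no alpha-amanitin records")
    table: dict[tuple[str, str], float] = {}
    for ga, gb in itertools.combinations_with_replacement(sorted(by_genus), 2):
        matches = total = 0
        pairs = (
            itertools.combinations(by_genus[ga], 2) if ga == gb
            else itertools.product(by_genus[ga], by_genus[gb])
        )
        for a, b in pairs:
            m, t = _anchored_identity(a, b)
            matches += m
            total += t
        ident = matches / total if total else 1.0
        table[(ga, gb)] = ident
        table[(gb, ga)] = ident
    return table
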