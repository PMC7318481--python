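"""MSDIN precursor mining: six-frame ORF scan, grammar parsing, PSSM screening.

Published surveys located MSDIN genes by manual TBLASTN annotation of
assembled unigenes. Here detection is reimplemented as a calibrated
position-specific scoring model: a 10-column leader PSSM (right-anchored,
so the terminal Pro of the leader always occupies column 10 even for 9-aa
Lepiota-type leaders), a 5-column PSSM over the recognition start
(consensus CVGDD), and a fixed bonus for a Pro-terminal core. Candidate
ORFs of 30-40 aa are exhaustively segmented under the grammar and kept when
the best segmentation scores above a threshold calibrated on the curated
precursor collection.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from Bio.Seq import Seq

from .records import (
    CORE_LENGTHS,
    LEADER_LENGTHS,
    PROTEIN_ALPHABET,
    RECOGNITION_LENGTHS,
    FixtureRow,
    PrecursorRecord,
    SequenceRecord,
)

AA = sorted(PROTEIN_ALPHABET)
_AA_INDEX = {a: i for i, a in enumerate(AA)}

#: log-odds bonus for a Pro-terminal core. About 94.5% of curated cores end
#: in Pro (the second POPB cleavage site) but exceptions exist (e.g. GFLFWA),
#: so the bonus is finite.
CORE_TERMINAL_PRO_BONUS = 2.0

#: Default mining threshold in nats: (minimum best-parse score over the
#: curated nonrepetitive precursor set) - 1, computed by
#: scripts/calibrate_threshold.py.
DEFAULT_THRESHOLD = 15.80

#: Leader-only acceptance threshold for pseudogene candidates, calibrated the
#: same way on leader scores alone.
DEFAULT_LEADER_THRESHOLD = 11.14


def residue_background(rows: Sequence[FixtureRow]) -> np.ndarray:
    """Residue frequencies over all curated precursors (the mining null).

    Decoy ORFs used for calibration are composition-matched shuffles, so
    log-odds against this background centres their scores near zero.
    """
    counts = Counter()
    for r in rows:
        counts.update(c for c in r.precursor if c in _AA_INDEX)
    total = sum(counts.values())
    bg = np.array([counts[a] / total for a in AA])
    return np.clip(bg, 1e-6, None)


@dataclass
class PSSM:
    """Positional log-odds matrix with additive pseudocounts.

    ``counts[j, k]`` is the number of training sequences with residue ``k``
    at column ``j``; column probabilities are
    ``(count + pseudocount) / (n + 20 * pseudocount)``.
    """

    counts: np.ndarray  # (length, 20)
    pseudocount: float
    background: np.ndarray  # (20,)
    right_anchored: bool = False

    @property
    def length(self) -> int:
        return self.counts.shape[0]

    @property
    def n(self) -> int:
        return int(round(self.counts[self.counts.sum(axis=1).argmax()].sum()))

    def probabilities(self) -> np.ndarray:
        denom = self.counts.sum(axis=1, keepdims=True) + 20 * self.pseudocount
        return (self.counts + self.pseudocount) / denom

    def score_matrix(self) -> np.ndarray:
        return np.log(self.probabilities() / self.background)

    def score(self, seq: str) -> float:
        """Log-odds of ``seq`` against the matrix.

        Right-anchored matrices align the last residue of ``seq`` to the last
        column; shorter sequences leave leading columns unscored. Characters
        outside the 20-letter alphabet (a premature stop ``*``) score as an
        unseen residue at that column.
        """
        sm = self.score_matrix()
        probs = self.probabilities()
        offset = self.length - len(seq) if self.right_anchored else 0
        total = 0.0
        for i, res in enumerate(seq):
            j = offset + i
            if j < 0 or j >= self.length:
                continue
            k = _AA_INDEX.get(res)
            if k is None:
                denom = self.counts[j].sum() + 20 * self.pseudocount
                total += math.log((self.pseudocount or 1e-3) / denom / self.background.mean())
            else:
                total += sm[j, k]
        return total


def _column_counts(seqs: Iterable[str], length: int, right_anchored: bool) -> np.ndarray:
    counts = np.zeros((length, 20))
    for s in seqs:
        offset = length - len(s) if right_anchored else 0
        for i, res in enumerate(s):
            j = offset + i
            if 0 <= j < length and res in _AA_INDEX:
                counts[j, _AA_INDEX[res]] += 1
    return counts


def build_leader_pssm(rows: Sequence[FixtureRow], pseudocount: float = 1.0,
                      background: np.ndarray | None = None) -> PSSM:
    """10-column PSSM over right-anchored leaders (column 10 = terminal P)."""
    leaders = [r.leader for r in rows if len(r.leader) in LEADER_LENGTHS]
    if len(leaders) < 20:
        raise ValueError(f"need >= 20 leaders to train the PSSM, got {len(leaders)}")
    if background is None:
        background = residue_background(rows)
    return PSSM(_column_counts(leaders, 10, True), pseudocount, background,
                right_anchored=True)


def build_recognition_pssm(rows: Sequence[FixtureRow], pseudocount: float = 1.0,
                           background: np.ndarray | None = None) -> PSSM:
    """5-column PSSM over recognition starts (consensus C22-V23-G24-D25-D26)."""
    starts = [r.recognition[:5] for r in rows]
    if len(starts) < 20:
        raise ValueError("need >= 20 rows to train the recognition PSSM")
    if background is None:
        background = residue_background(rows)
    return PSSM(_column_counts(starts, 5, False), pseudocount, background)


def build_recognition_end_pssm(rows: Sequence[FixtureRow], pseudocount: float = 1.0,
                               background: np.ndarray | None = None) -> PSSM:
    """8-column PSSM over recognition ends (consensus ..L31 T32 R33 G34 E35 - L37 C38).

    The recognition tail is the same for every candidate segmentation of a
    precursor, so this component sharpens the discrimination of genuine
    precursors from composition-matched decoys without influencing which
    segmentation wins.
    """
    ends = [r.recognition[-8:] for r in rows]
    if len(ends) < 20:
        raise ValueError("need >= 20 rows to train the recognition-end PSSM")
    if background is None:
        background = residue_background(rows)
    return PSSM(_column_counts(ends, 8, True), pseudocount, background,
                right_anchored=True)


def six_frame_orfs(record: SequenceRecord, min_aa: int = 10
                   ) -> list[tuple[str, int, str, tuple[int, int]]]:
    """All Met-to-stop ORFs of >= min_aa residues in all six reading frames.

    Returns (strand, frame, peptide, (start, end)) with 0-based half-open
    nucleotide coordinates on the forward strand; the peptide excludes the
    stop. The stop codon is required (open 3' ends are not reported).
    """
    if record.moltype != "dna":
        raise ValueError("six_frame_orfs requires a dna record")
    if min_aa < 10:
        raise ValueError("min_aa must be >= 10")
    n = len(record.seq)
    results = []
    for strand, seq in (("+", record.seq), ("-", str(Seq(record.seq).reverse_complement()))):
        for frame in range(3):
            aa = str(Seq(seq[frame:frame + 3 * ((n - frame) // 3)]).translate())
            starts: list[int] = []
            for i, res in enumerate(aa):
                if res == "M":
                    starts.append(i)
                elif res == "*":
                    for start in starts:  # every Met-to-stop translation
                        pep = aa[start:i]
                        if len(pep) >= min_aa:
                            nt0 = frame + 3 * start
                            nt1 = frame + 3 * (i + 1)  # include stop codon
                            if strand == "-":
                                nt0, nt1 = n - nt1, n - nt0
                            results.append((strand, frame, pep, (nt0, nt1)))
                    starts.clear()
    return results


def _readthrough_orfs(record: SequenceRecord, max_aa: int = 40
                      ) -> list[tuple[str, int, str, tuple[int, int]]]:
    """Met-initiated translations containing exactly one internal stop.

    Used to recover pseudogenes whose core carries a premature stop (e.g. a
    TGG Trp codon mutated to TGA): the translation is extended through the
    first stop to the next one, keeping '*' in place.
    """
    n = len(record.seq)
    results = []
    for strand, seq in (("+", record.seq), ("-", str(Seq(record.seq).reverse_complement()))):
        for frame in range(3):
            aa = str(Seq(seq[frame:frame + 3 * ((n - frame) // 3)]).translate())
            for i, res in enumerate(aa):
                if res != "M":
                    continue
                window = aa[i:i + max_aa + 1]
                first = window.find("*")
                if first < 0:
                    continue
                second = window.find("*", first + 1)
                if second < 0:
                    continue
                pep = window[:second]
                if "*" in pep[:-1] and pep.count("*") == 1:
                    nt0 = frame + 3 * i
                    nt1 = frame + 3 * (i + second + 1)
                    if strand == "-":
                        nt0, nt1 = n - nt1, n - nt0
                    results.append((strand, frame, pep, (nt0, nt1)))
    return results


def parse_precursor(aa: str, leader_pssm: PSSM, recog_pssm: PSSM,
                    recog_end_pssm: PSSM | None = None,
                    pro_bonus: float = CORE_TERMINAL_PRO_BONUS
                    ) -> tuple[str, str, str, float]:
    """Best grammar segmentation of a precursor peptide.

    Enumerates every split with leader in {9, 10}, core in 6..11 and
    recognition (the remainder) in 13..18, scores each as leader log-odds +
    recognition-start log-odds (+ recognition-end log-odds when that PSSM is
    given, a constant across splits) + Pro bonus, and returns the argmax.
    Ties go to a Pro-terminal core, then to the longer leader.
    """
    if not 30 <= len(aa) <= 40:
        raise ValueError(f"precursor length {len(aa)} outside 30-40")
    if not aa.startswith("M"):
        raise ValueError("precursor must start with Met")
    end_score = recog_end_pssm.score(aa[-8:]) if recog_end_pssm else 0.0
    best = None
    for llen in LEADER_LENGTHS:
        for clen in CORE_LENGTHS:
            rlen = len(aa) - llen - clen
            if rlen not in RECOGNITION_LENGTHS:
                continue
            leader, core = aa[:llen], aa[llen:llen + clen]
            recog = aa[llen + clen:]
            score = (leader_pssm.score(leader) + recog_pssm.score(recog[:5])
                     + end_score)
            ends_pro = core.endswith("P")
            if ends_pro:
                score += pro_bonus
            key = (score, ends_pro, llen)
            if best is None or key > best[0]:
                best = (key, (leader, core, recog, score))
    if best is None:
        raise ValueError(f"no admissible segmentation for length {len(aa)}")
    return best[1]


def build_pssms(rows: Sequence[FixtureRow], pseudocount: float = 1.0
                ) -> tuple[PSSM, PSSM, PSSM]:
    """(leader, recognition-start, recognition-end) PSSMs from curated rows."""
    background = residue_background(rows)
    return (
        build_leader_pssm(rows, pseudocount, background),
        build_recognition_pssm(rows, pseudocount, background),
        build_recognition_end_pssm(rows, pseudocount, background),
    )


def mine_msdins(records: Iterable[SequenceRecord], leader_pssm: PSSM,
                recog_pssm: PSSM, recog_end_pssm: PSSM | None = None,
                threshold: float = DEFAULT_THRESHOLD,
                leader_threshold: float = DEFAULT_LEADER_THRESHOLD,
                min_len: int = 30, max_len: int = 40) -> list[PrecursorRecord]:
    """Screen nucleotide records for MSDIN precursor ORFs.

    Intact ORFs of min_len..max_len aa whose best segmentation scores >=
    threshold become PrecursorRecords. Met-initiated translations with a
    single internal stop are screened on the leader alone and reported with
    is_pseudogene=True (the stop is retained in the core/recognition).
    """
    hits: list[PrecursorRecord] = []
    for record in records:
        candidates = [
            (s, f, pep, c, False)
            for s, f, pep, c in six_frame_orfs(record, min_aa=min_len)
            if min_len <= len(pep) <= max_len
        ]
        candidates += [
            (s, f, pep, c, True)
            for s, f, pep, c in _readthrough_orfs(record, max_aa=max_len)
            if min_len <= len(pep) <= max_len
        ]
        for strand, frame, pep, coords, pseudo in candidates:
            try:
                leader, core, recog, score = parse_precursor(
                    pep, leader_pssm, recog_pssm, recog_end_pssm)
            except ValueError:
                continue
            if pseudo:
                if "*" not in core + recog:
                    continue
                if leader_pssm.score(leader) < leader_threshold:
                    continue
            elif score < threshold:
                continue
            hits.append(PrecursorRecord(
                contig_id=record.id, strand=strand, frame=frame,
                leader=leader, core=core, recognition=recog,
                is_pseudogene=pseudo, parse_score=score, coords=coords,
            ))
    return hits


def calibrate_thresholds(rows: Sequence[FixtureRow],
                         margin: float = 1.0) -> tuple[float, float]:
    """(full, leader-only) thresholds: min curated score minus ``margin``."""
    leader_pssm, recog_pssm, end_pssm = build_pssms(rows)
    full, leader_only = [], []
    for r in rows:
        if r.is_pseudogene:
            continue
        _, _, _, score = parse_precursor(r.precursor, leader_pssm, recog_pssm,
                                         end_pssm)
        full.append(score)
        leader_only.append(leader_pssm.score(r.leader))
    return min(full) - margin, min(leader_only) - margin
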