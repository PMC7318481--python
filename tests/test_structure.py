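import numpy as np
import pytest
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from msdin.records import SequenceRecord
from msdin.simulate import insert_introns, reverse_translate
from msdin.structure import (
    SplicedAlignmentError,
    extract_cds,
    local_align_score,
    spliced_align,
    translated_sw_search,
)
from oracles import gotoh_local_score


def _random_cds(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def test_identical_sequences_give_single_exon(rng):
    cds = _random_cds(rng, 120)
    model = spliced_align(cds, cds)
    assert model.exons == [(0, 120)] and model.n_introns == 0


def test_three_inserted_introns_are_recovered_exactly(rng):
    cds = _random_cds(rng, 300)
    genomic, truth = insert_introns(cds, 3, rng)
    model = spliced_align(cds, genomic)
    assert model.exons == truth.exons
    assert extract_cds(model, genomic) == cds
    for s, e in model.introns:
        assert genomic[s:s + 2] == "GT" and genomic[e - 2:e] == "AG"


def test_popa_like_structure_with_18_introns(rng):
    cds = _random_cds(rng, 2100)
    genomic, truth = insert_introns(cds, 18, rng)
    model = spliced_align(cds, genomic)
    assert (model.n_exons, model.n_introns) == (19, 18)
    assert model.exons == truth.exons


def test_round_trip_over_200_synthetic_genes():
    """100% intron-count and >= 99% boundary recovery (0-18 introns)."""
    count_ok = boundaries_ok = boundaries_total = 0
    for i in range(200):
        rng = np.random.default_rng(1000 + i)
        n_introns = int(rng.integers(0, 19))
        cds = _random_cds(rng, max(300, n_introns * 40 + 60))
        genomic, truth = insert_introns(cds, n_introns, rng)
        model = spliced_align(cds, genomic)
        count_ok += model.n_introns == truth.n_introns
        true_b = {b for iv in truth.introns for b in iv}
        got_b = {b for iv in model.introns for b in iv}
        boundaries_total += len(true_b)
        boundaries_ok += len(true_b & got_b)
    assert count_ok == 200
    assert boundaries_ok / max(boundaries_total, 1) >= 0.99


def test_failure_modes_are_informative(rng):
    cds = _random_cds(rng, 120)
    with pytest.raises(SplicedAlignmentError, match="longer"):
        spliced_align(cds + "A", cds)
    # genomic with a non-GT..AG insertion admits no decomposition
    genomic = cds[:60] + "CCTTTTTTCC" + cds[60:]
    with pytest.raises(SplicedAlignmentError, match="decomposition"):
        spliced_align(cds, genomic)


def test_smith_waterman_scores_match_gotoh_oracle(rng):
    aa = "ACDEFGHIKLMNPQRSTVWY"
    for _ in range(50):
        a = "".join(aa[i] for i in rng.integers(0, 20, size=rng.integers(10, 31)))
        b = "".join(aa[i] for i in rng.integers(0, 20, size=rng.integers(10, 31)))
        assert local_align_score(a, b) == pytest.approx(gotoh_local_score(a, b))


def test_self_match_score_is_the_diagonal_sum():
    blosum = substitution_matrices.load("BLOSUM62")
    query = "MSDINATRLPIWGIGCNP"
    expected = sum(blosum[c][c] for c in query)
    assert local_align_score(query, query) == pytest.approx(expected)


def test_translated_search_finds_backtranslated_query(rng):
    query = "MSDINATRLPIWGIGCNPCVGDDVTSVLTRGEALC"
    cds = reverse_translate(query, rng)
    flank = _random_cds(rng, 80)
    record = SequenceRecord("c", flank + cds + _random_cds(rng, 80))
    hits = translated_sw_search(query, [record], min_score=50)
    assert hits and hits[0].score == pytest.approx(local_align_score(query, query))


def test_translated_search_score_invariant_under_reverse_complement(rng):
    query = "MSDINATRLPIWGIGCNPCVGDDVTSVLTRGEALC"
    cds = reverse_translate(query, rng)
    record = SequenceRecord("c", _random_cds(rng, 60) + cds + _random_cds(rng, 60))
    flipped = SequenceRecord("c", str(Seq(record.seq).reverse_complement()))
    s1 = translated_sw_search(query, [record], min_score=50)[0]
    s2 = translated_sw_search(query, [flipped], min_score=50)[0]
    assert s1.score == s2.score
    assert {s1.strand, s2.strand} == {"+", "-"}


def test_unrelated_contig_scores_below_a_calibrated_floor(rng):
    """Empirical null: random contigs never reach the self-match score range."""
    query = "MSDINATRLPIWGIGCNPCVGDDVTSVLTRGEALC"
    null_scores = []
    for _ in range(20):
        record = SequenceRecord("n", _random_cds(rng, 600))
        hits = translated_sw_search(query, [record], min_score=0)
        null_scores.append(max(h.score for h in hits))
    assert max(null_scores) < local_align_score(query, query) / 2


def test_empty_query_rejected():
    with pytest.raises(ValueError):
        translated_sw_search("", [SequenceRecord("a", "ACGTACGTACGT")])
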