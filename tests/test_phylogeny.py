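import math

import numpy as np
import pytest
from skbio import DistanceMatrix

from msdin.phylogeny import (
    SaturationError,
    bipartitions,
    bootstrap_support,
    is_monophyletic,
    neighbor_joining,
    pairwise_distance,
)
from msdin.simulate import TreeSim, evolve_on_tree, pop_hgt_scenario, simulate_alignment_on_tree
from oracles import random_additive_tree, tree_path_lengths


def _seqs_with_p(p_mismatch, n=200):
    k = int(round(p_mismatch * n))
    a = "A" * n
    b = "G" * k + "A" * (n - k)
    return {"x": a, "y": b}


def test_identical_sequences_have_zero_distance():
    aln = {"x": "ACGTACGT", "y": "ACGTACGT", "z": "ACGTACGT"}
    for model in ("p", "JC69", "K80"):
        assert pairwise_distance(aln, model).data.max() == 0.0


def test_jc69_closed_form_at_p_10_percent():
    dm = pairwise_distance(_seqs_with_p(0.1), "JC69")
    assert dm["x", "y"] == pytest.approx(0.107326, abs=1e-6)


@pytest.mark.parametrize("p", [0.05, 0.2, 0.5, 0.7])
def test_jc_correction_never_shrinks_p(p):
    dm_p = pairwise_distance(_seqs_with_p(p), "p")
    dm_jc = pairwise_distance(_seqs_with_p(p), "JC69")
    assert dm_jc["x", "y"] >= dm_p["x", "y"]


def test_saturated_pair_raises_rather_than_returning_infinity():
    with pytest.raises(SaturationError, match="x/y"):
        pairwise_distance(_seqs_with_p(0.8), "JC69")


def test_gapped_sites_are_skipped_pairwise():
    aln = {"x": "ACGT-CGT", "y": "ACGTAC-T", "z": "ACGTACGT"}
    dm = pairwise_distance(aln, "p")
    assert dm["x", "y"] == 0.0  # only ungapped columns compared


def test_k80_reduces_to_jc_under_equal_ts_tv():
    # 2 transitions + 4 transversions over 60 sites
    a = "A" * 60
    b = "G" * 2 + "C" * 2 + "T" * 2 + "A" * 54
    P, Q = 2 / 60, 4 / 60
    expected = -0.5 * math.log((1 - 2 * P - Q) * math.sqrt(1 - 2 * Q))
    dm = pairwise_distance({"x": a, "y": b}, "K80")
    assert dm["x", "y"] == pytest.approx(expected)


def test_nj_recovers_random_additive_matrices_exactly():
    """NJ on 100 additive matrices (<= 12 taxa): exact topology and path lengths."""
    for i in range(100):
        rng = np.random.default_rng(3000 + i)
        n_taxa = int(rng.integers(4, 13))
        true_tree = random_additive_tree(rng, n_taxa)
        true_paths = tree_path_lengths(true_tree)
        labels = sorted({t.name for t in true_tree.tips()})
        dm = DistanceMatrix(
            [[0 if a == b else true_paths[tuple(sorted((a, b)))] for b in labels]
             for a in labels], ids=labels)
        est = neighbor_joining(dm)
        assert bipartitions(est) == bipartitions(true_tree)
        est_paths = tree_path_lengths(est)
        for pair, d in true_paths.items():
            assert est_paths[pair] == pytest.approx(d, abs=1e-8)


def test_nj_agrees_with_reference_implementation_on_additive_input():
    rng = np.random.default_rng(11)
    true_tree = random_additive_tree(rng, 8)
    paths = tree_path_lengths(true_tree)
    labels = sorted({t.name for t in true_tree.tips()})
    dm = DistanceMatrix(
        [[0 if a == b else paths[tuple(sorted((a, b)))] for b in labels]
         for a in labels], ids=labels)
    from skbio.tree import nj as skbio_nj

    assert bipartitions(neighbor_joining(dm)) == bipartitions(skbio_nj(dm))


def test_nj_is_invariant_under_label_permutation():
    rng = np.random.default_rng(23)
    tree = random_additive_tree(rng, 7)
    paths = tree_path_lengths(tree)
    labels = sorted({t.name for t in tree.tips()})
    mat = [[0 if a == b else paths[tuple(sorted((a, b)))] for b in labels]
           for a in labels]
    dm = DistanceMatrix(mat, ids=labels)
    perm = list(rng.permutation(len(labels)))
    dm_perm = DistanceMatrix(
        [[mat[i][j] for j in perm] for i in perm],
        ids=[labels[i] for i in perm])
    assert bipartitions(neighbor_joining(dm)) == bipartitions(neighbor_joining(dm_perm))


def test_nj_rejects_asymmetric_matrix():
    dm = DistanceMatrix([[0, 1, 2], [1, 0, 3], [2, 3, 0]], ids=list("abc"))
    dm.data[0, 1] = 5.0
    with pytest.raises(ValueError):
        neighbor_joining(dm)


FOUR_CLADE_NEWICK = (
    "(((a1:0.02,a2:0.02):0.2,(b1:0.02,b2:0.02):0.2):0.1,"
    "((c1:0.02,c2:0.02):0.2,(d1:0.02,d2:0.02):0.2):0.1);"
)


def test_bootstrap_is_deterministic_for_a_fixed_seed():
    rng = np.random.default_rng(5)
    aln = evolve_on_tree(FOUR_CLADE_NEWICK, 400, rng)
    t1 = bootstrap_support(aln, n_reps=100, seed=9)
    t2 = bootstrap_support(aln, n_reps=100, seed=9)
    s1 = sorted(n.support for n in t1.non_tips(include_self=False))
    s2 = sorted(n.support for n in t2.non_tips(include_self=False))
    assert s1 == s2
    assert all(0.0 <= s <= 1.0 for s in s1)


def test_planted_clades_reach_high_support():
    rng = np.random.default_rng(6)
    aln = evolve_on_tree(FOUR_CLADE_NEWICK, 600, rng)
    tree = bootstrap_support(aln, n_reps=100, seed=1)
    for clade in (("a1", "a2"), ("b1", "b2"), ("c1", "c2"), ("d1", "d2")):
        assert is_monophyletic(tree, clade)
        node = tree.lca([tree.find(n) for n in clade])
        assert node.support >= 0.9


def test_trivial_monophyly_queries():
    rng = np.random.default_rng(8)
    aln = evolve_on_tree(FOUR_CLADE_NEWICK, 200, rng)
    tree = neighbor_joining(pairwise_distance(aln))
    leaves = sorted(aln)
    assert is_monophyletic(tree, [leaves[0]])
    assert is_monophyletic(tree, leaves)
    with pytest.raises(KeyError):
        is_monophyletic(tree, ["nonexistent"])


def test_hgt_scenario_shows_phylogenetic_incongruence():
    """Transferred-locus copies cluster while the vertical locus follows the
    species tree, in >= 90% of seeded replicates."""
    successes = 0
    n_reps = 20
    for rep in range(n_reps):
        rng = np.random.default_rng([2024, rep])
        aln, popa_labels, popb_toxin = pop_hgt_scenario(rng, n_sites=600)
        tree = neighbor_joining(pairwise_distance(aln, "JC69"))
        ok = is_monophyletic(tree, popb_toxin)
        ok &= is_monophyletic(tree, {f"am{i}_POPA" for i in range(1, 6)})
        ok &= is_monophyletic(tree, {"gal1_POPA", "gal2_POPA", "og1_POPA"})
        ok &= is_monophyletic(tree, {"lep1_POPA", "lep2_POPA", "og2_POPA"})
        successes += ok
    assert successes / n_reps >= 0.9


def test_hgt_grafting_changes_only_the_transferred_locus():
    sim = TreeSim(newick=FOUR_CLADE_NEWICK, n_sites=50,
                  hgt_clade=("d1", "d2"), hgt_dest=("a1", "a2"))
    rng = np.random.default_rng(3)
    out = simulate_alignment_on_tree(sim, rng)
    assert set(out) == {"vertical", "transferred"}
    assert set(out["vertical"]) == set(out["transferred"])
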