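"""Distance-based phylogenetics: p/JC69/K80 distances, neighbor joining,
site-resampling bootstrap, and monophyly queries.

This is a deliberate desk-scale surrogate for the likelihood analyses used
in published POP/MSDIN phylogenies (HKY/GTR + I + G in RAxML/MrBayes):
clade structure, not branch support percentages on real accessions, is the
claim these tools make.
"""

from __future__ import annotations

import math
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from skbio import DistanceMatrix, TreeNode

PURINES = {"A", "G"}
GAP_CHARS = {"-", ".", "N"}


class SaturationError(ValueError):
    """A pairwise distance is undefined (substitution saturation)."""


def _site_pairs(a: str, b: str):
    for x, y in zip(a, b):
        if x in GAP_CHARS or y in GAP_CHARS:
            continue
        yield x, y


def pairwise_distance(aln: Mapping[str, str], model: str = "JC69") -> DistanceMatrix:
    """Pairwise evolutionary distances from an alignment.

    Models: ``p`` (mismatch fraction), ``JC69`` (d = -3/4 ln(1 - 4p/3)),
    ``K80`` (d = -1/2 ln((1-2P-Q) sqrt(1-2Q)) with P transitions, Q
    transversions). Sites with a gap in either member are skipped pairwise.
    """
    labels = list(aln)
    lengths = {len(s) for s in aln.values()}
    if len(lengths) != 1:
        raise ValueError("alignment sequences differ in length")
    model = model.upper() if model.lower() != "p" else "p"
    mat = np.zeros((len(labels), len(labels)))
    for i, j in combinations(range(len(labels)), 2):
        pairs = list(_site_pairs(aln[labels[i]], aln[labels[j]]))
        if not pairs:
            raise ValueError(f"no comparable sites for {labels[i]}/{labels[j]}")
        n = len(pairs)
        mismatch = sum(x != y for x, y in pairs)
        p = mismatch / n
        if model == "p":
            d = p
        elif model == "JC69":
            if p >= 0.75:
                raise SaturationError(f"saturated pair {labels[i]}/{labels[j]} (p={p:.3f})")
            d = -0.75 * math.log(1 - 4 * p / 3)
        elif model == "K80":
            ts = sum(x != y and (x in PURINES) == (y in PURINES) for x, y in pairs)
            P, Q = ts / n, (mismatch - ts) / n
            if 1 - 2 * P - Q <= 0 or 1 - 2 * Q <= 0:
                raise SaturationError(f"saturated pair {labels[i]}/{labels[j]}")
            d = -0.5 * math.log((1 - 2 * P - Q) * math.sqrt(1 - 2 * Q))
        else:
            raise ValueError(f"unknown model {model!r}")
        mat[i, j] = mat[j, i] = d
    return DistanceMatrix(mat, ids=labels)


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining.

    Negative branch lengths are clamped to zero with the deficit moved to
    the sister edge, keeping the path length between the joined pair.
    """
    labels = list(dm.ids)
    if len(labels) < 3:
        raise ValueError("need >= 3 taxa")
    d = np.asarray(dm.data, dtype=float).copy()
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix is not symmetric")
    nodes = [TreeNode(name=l) for l in labels]
    active = list(range(len(labels)))
    while len(active) > 2:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        ai, aj = np.unravel_index(np.argmin(q), q.shape)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = sub[ai, aj]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2 * (m - 2))
        lj = dij - li
        # clamp negatives, shifting the remainder to the sister edge
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        parent = TreeNode(children=[nodes[i], nodes[j]])
        nodes[i].length, nodes[j].length = float(li), float(lj)
        # distances from the new node to the rest
        new_row = np.full(d.shape[0], np.nan)
        for ak in range(m):
            k = active[ak]
            if k in (i, j):
                continue
            new_row[k] = 0.5 * (d[i, k] + d[j, k] - dij)
        d[i, :] = new_row
        d[:, i] = new_row
        d[i, i] = 0.0
        nodes[i] = parent
        active.remove(j)
    i, j = active
    root = TreeNode(children=[nodes[i], nodes[j]])
    nodes[i].length = 0.0
    nodes[j].length = float(max(d[i, j], 0.0))
    return root


def tip_names(tree: TreeNode) -> set[str]:
    return {t.name for t in tree.tips()}


def bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial bipartitions, each canonicalised to the side not
    containing the lexicographically smallest leaf."""
    leaves = tip_names(tree)
    ref = min(leaves)
    parts = set()
    for node in tree.non_tips(include_self=False):
        side = {t.name for t in node.tips()}
        if len(side) < 2 or len(leaves) - len(side) < 2:
            continue
        if ref in side:
            side = leaves - side
        parts.add(frozenset(side))
    return parts


def is_monophyletic(tree: TreeNode, labels: Sequence[str]) -> bool:
    """True iff some edge bipartition separates exactly ``labels``."""
    label_set = set(labels)
    leaves = tip_names(tree)
    unknown = label_set - leaves
    if unknown:
        raise KeyError(f"labels not in tree: {sorted(unknown)}")
    if len(label_set) in (0, 1, len(leaves)):
        return True
    if len(label_set) == len(leaves) - 1:
        return True  # complement of a single tip
    ref = min(leaves)
    query = leaves - label_set if ref in label_set else label_set
    return frozenset(query) in bipartitions(tree)


def bootstrap_support(aln: Mapping[str, str], n_reps: int = 100, seed: int = 0,
                      model: str = "JC69") -> TreeNode:
    """NJ tree with bipartition supports from site resampling.

    Sites are resampled with replacement per replicate; the support of each
    internal edge of the full-data tree is the fraction of replicate trees
    containing the same bipartition. Replicate r draws from a dedicated
    stream offset so runs are reproducible for a fixed seed.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    n_sites = len(next(iter(aln.values())))
    if n_sites < 4:
        raise ValueError("alignment shorter than 4 sites")
    tree = neighbor_joining(pairwise_distance(aln, model))
    counts: dict[frozenset[str], int] = {bp: 0 for bp in bipartitions(tree)}
    for rep in range(n_reps):
        rng = np.random.default_rng([seed, rep])
        idx = rng.integers(0, n_sites, size=n_sites)
        sub = {k: "".join(v[i] for i in idx) for k, v in aln.items()}
        try:
            rep_tree = neighbor_joining(pairwise_distance(sub, model))
        except SaturationError:
            continue
        for bp in bipartitions(rep_tree):
            if bp in counts:
                counts[bp] += 1
    leaves = tip_names(tree)
    ref = min(leaves)
    for node in tree.non_tips(include_self=False):
        side = {t.name for t in node.tips()}
        if len(side) < 2 or len(leaves) - len(side) < 2:
            node.support = 1.0
            continue
        key = frozenset(leaves - side if ref in side else side)
        node.support = counts.get(key, 0) / n_reps
    return tree
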