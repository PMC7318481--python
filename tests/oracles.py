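"""Independent brute-force oracles used by the tests.

These deliberately avoid the code paths they verify: translation and ORF
scanning are written out longhand, Smith-Waterman is a plain Gotoh dynamic
program, and tree path lengths are computed by explicit leaf-to-leaf walks.
"""

from __future__ import annotations

import itertools

from Bio.Align import substitution_matrices
from Bio.Data.CodonTable import standard_dna_table

_CODON = dict(standard_dna_table.forward_table)
for stop in standard_dna_table.stop_codons:
    _CODON[stop] = "*"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def translate(dna: str) -> str:
    return "".join(_CODON.get(dna[i:i + 3], "X") for i in range(0, len(dna) - 2, 3))


def brute_force_orfs(seq: str, min_aa: int) -> set[tuple[str, str]]:
    """{(strand, peptide)} for every Met-to-stop translation in six frames."""
    out = set()
    for strand, s in (("+", seq), ("-", seq.translate(_COMPLEMENT)[::-1])):
        for frame in range(3):
            aa = translate(s[frame:])
            for start in range(len(aa)):
                if aa[start] != "M":
                    continue
                stop = aa.find("*", start)
                if stop < 0:
                    continue
                pep = aa[start:stop]
                if len(pep) >= min_aa:
                    out.add((strand, pep))
    return out


def gotoh_local_score(a: str, b: str, gap_open: int = 11, gap_extend: int = 1
                      ) -> float:
    """Affine-gap local alignment score; a gap of length k costs open + k*extend."""
    n, m = len(a), len(b)
    NEG = float("-inf")
    best = 0.0
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consume a)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consume b)
    first = gap_open + gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            X[i][j] = max(M[i - 1][j] - first, X[i - 1][j] - gap_extend)
            Y[i][j] = max(M[i][j - 1] - first, Y[i][j - 1] - gap_extend)
            sub = _BLOSUM62[a[i - 1]][b[j - 1]]
            M[i][j] = max(0.0, M[i - 1][j - 1] + sub, X[i][j], Y[i][j])
            best = max(best, M[i][j])
    return best


def expansion_set(iupac: str) -> set[str]:
    from Bio.Data.IUPACData import ambiguous_dna_values

    return {
        "".join(c) for c in itertools.product(
            *(sorted(ambiguous_dna_values[ch]) for ch in iupac))
    }


def tree_path_lengths(tree) -> dict[tuple[str, str], float]:
    """Leaf-to-leaf path lengths by explicit root-path walks."""
    paths = {}
    for tip in tree.tips():
        node, path = tip, []
        while node.parent is not None:
            path.append(node)
            node = node.parent
        paths[tip.name] = path
    out = {}
    for x, y in itertools.combinations(sorted(paths), 2):
        px, py = paths[x], paths[y]
        shared = {id(n) for n in px} & {id(n) for n in py}
        d = sum((n.length or 0.0) for n in px if id(n) not in shared)
        d += sum((n.length or 0.0) for n in py if id(n) not in shared)
        out[(x, y)] = d
    return out


def random_additive_tree(rng, n_taxa: int):
    """A random binary tree with positive branch lengths (skbio TreeNode)."""
    from skbio import TreeNode

    nodes = [TreeNode(name=f"t{i}") for i in range(n_taxa)]
    for node in nodes:
        node.length = round(float(rng.uniform(0.1, 2.0)), 3)
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = TreeNode(children=[nodes[i], nodes[j]])
        parent.length = round(float(rng.uniform(0.1, 2.0)), 3)
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    return TreeNode(children=nodes)
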