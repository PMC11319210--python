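"""Distance-based neighbor-joining trees.

Used for accession trees built on PAV Jaccard distances and for
centromere-monomer trees built on normalized edit distances.  The
neighbor-joining implementation is the classical Saitou--Nei agglomeration
with deterministic tie-breaking, so identical inputs always yield identical
Newick output.
"""

from __future__ import annotations

import edlib
import numpy as np
from skbio import DistanceMatrix, TreeNode

from .errors import InputError

_COMP = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMP)[::-1]


def monomer_distance(a: str, b: str) -> float:
    """Normalized edit distance Levenshtein(a, b) / max(|a|, |b|), in [0, 1]."""
    if not a or not b:
        raise InputError("monomer_distance needs non-empty sequences")
    d = edlib.align(a.upper(), b.upper(), task="distance")["editDistance"]
    return d / max(len(a), len(b))


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Classical Saitou--Nei neighbor joining on a (possibly non-metric)
    distance matrix.

    At each step the pair minimizing
    ``Q(i, j) = (m - 2) d(i, j) - sum_k d(i, k) - sum_k d(j, k)``
    is joined; Q ties are broken by lexicographic order of node labels
    (internal nodes inherit the smallest leaf label beneath them).
    Negative branch-length estimates are clamped to zero and counted in
    the ``negative_branches_clamped`` attribute of the returned root.
    """
    labels = list(dm.ids)
    if len(labels) < 3:
        raise InputError("neighbor joining needs >= 3 taxa")
    d = np.array(dm.data, dtype=float)
    if not np.allclose(d, d.T, atol=1e-12):
        raise InputError("distance matrix is not symmetric")

    nodes = [TreeNode(name=lab) for lab in labels]
    keys = list(labels)           # tie-break key per active node
    n_clamped = 0

    def clamp(x: float) -> float:
        nonlocal n_clamped
        if x < 0:
            n_clamped += 1
            return 0.0
        return x

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * d[i, j] - r[i] - r[j]
                ki, kj = sorted((keys[i], keys[j]))
                cand = (q, ki, kj, i, j)
                if best is None or cand[:3] < best[:3]:
                    best = cand
        _, _, _, i, j = best
        li = clamp(d[i, j] / 2 + (r[i] - r[j]) / (2 * (m - 2)))
        lj = clamp(d[i, j] - (d[i, j] / 2 + (r[i] - r[j]) / (2 * (m - 2))))
        nodes[i].length, nodes[j].length = li, lj
        parent = TreeNode(children=[nodes[i], nodes[j]])
        # distances from the new node to every remaining node
        dnew = 0.5 * (d[i] + d[j] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d = np.pad(d[np.ix_(keep, keep)], ((0, 1), (0, 1)))
        d[-1, :-1] = d[:-1, -1] = dnew[keep]
        new_key = min(keys[i], keys[j])
        nodes = [nodes[k] for k in keep] + [parent]
        keys = [keys[k] for k in keep] + [new_key]

    # join the last three nodes on an unrooted (trifurcating) root
    (a, b, c) = range(3)
    la = clamp((d[a, b] + d[a, c] - d[b, c]) / 2)
    lb = clamp((d[a, b] + d[b, c] - d[a, c]) / 2)
    lc = clamp((d[a, c] + d[b, c] - d[a, b]) / 2)
    for node, ln in zip(nodes, (la, lb, lc)):
        node.length = ln
    root = TreeNode(children=list(nodes))
    root.negative_branches_clamped = n_clamped
    return root
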