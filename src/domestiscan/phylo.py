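"""Protein distances, neighbor joining, Newick I/O and domain identity.

Distances are pairwise p-distances (mismatches over compared columns,
skipping columns gapped in either sequence) or Poisson-corrected
-ln(1 - p).  Neighbor joining follows the Studier–Keppler formulation:
repeatedly join the pair minimizing Q(i, j) = (n - 2) d(i, j) - r_i - r_j,
which reconstructs any additive (tree-realizable) distance matrix exactly.
Trees are scikit-bio ``TreeNode`` objects (unrooted, trifurcating root)
and serialize to Newick.
"""

from __future__ import annotations

import io
import math

import numpy as np
from skbio import DistanceMatrix, TreeNode

from .errors import DomestiscanError

__all__ = [
    "protein_distance",
    "neighbor_joining",
    "to_newick",
    "read_newick",
    "tree_splits",
    "domain_identity",
]


def protein_distance(alignment: dict[str, str], model: str = "poisson") -> DistanceMatrix:
    """Pairwise distances over an aligned protein set.

    ``model`` is ``"p"`` (proportion of differing compared columns) or
    ``"poisson"`` (-ln(1 - p); raises when p >= 1).  Columns with a gap in
    either member of a pair are skipped; a pair with no compared columns
    is an error.
    """
    if model not in ("p", "poisson"):
        raise DomestiscanError(f"unknown distance model {model!r}")
    labels = list(alignment)
    if len(labels) < 3:
        raise DomestiscanError("need >= 3 sequences")
    seqs = [alignment[l].upper() for l in labels]
    if len({len(s) for s in seqs}) != 1:
        raise DomestiscanError("sequences are not aligned (unequal lengths)")
    arr = np.array([list(s) for s in seqs])
    gap = (arr == "-") | (arr == ".")
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mask = ~(gap[i] | gap[j])
            compared = int(mask.sum())
            if compared == 0:
                raise DomestiscanError(
                    f"{labels[i]} and {labels[j]} share no compared columns"
                )
            p = float(((arr[i] != arr[j]) & mask).sum()) / compared
            if model == "poisson":
                if p >= 1.0:
                    raise DomestiscanError(
                        f"p-distance {p} >= 1 between {labels[i]} and {labels[j]}; "
                        "Poisson correction undefined"
                    )
                p = -math.log(1.0 - p)
            d[i, j] = d[j, i] = p
    return DistanceMatrix(d, ids=labels)


def _clip_pair(vi: float, vj: float) -> tuple[float, float]:
    """Clip a negative branch to 0, moving the deficit to its sibling."""
    if vi < 0:
        vj += vi
        vi = 0.0
    if vj < 0:
        vi += vj
        vj = 0.0
    return max(vi, 0.0), max(vj, 0.0)


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Neighbor-joining tree from a distance matrix (Studier–Keppler).

    Ties in Q are broken toward the smallest (i, j) pair in input label
    order, making the topology deterministic.  Negative branch lengths are
    clipped to zero with the deficit added to the sibling branch, which
    preserves the joined pair's distance.  The returned tree is unrooted
    (trifurcating root).
    """
    D = np.array(dm.data, dtype=float)
    if not np.allclose(D, D.T) or not np.isfinite(D).all():
        raise DomestiscanError("distance matrix must be symmetric and finite")
    labels = list(dm.ids)
    if len(labels) < 3:
        raise DomestiscanError("need >= 3 taxa")
    nodes: list[TreeNode] = [TreeNode(name=l) for l in labels]

    while len(nodes) > 3:
        n = len(nodes)
        r = D.sum(axis=1)
        best = None
        best_q = math.inf
        for i in range(n):
            for j in range(i + 1, n):
                q = (n - 2) * D[i, j] - r[i] - r[j]
                if q < best_q - 1e-12:
                    best_q = q
                    best = (i, j)
        i, j = best
        vi = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (n - 2))
        vj = D[i, j] - vi
        vi, vj = _clip_pair(vi, vj)
        nodes[i].length = vi
        nodes[j].length = vj
        new_node = TreeNode(children=[nodes[i], nodes[j]])
        new_row = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(n) if k not in (i, j)]
        D2 = np.zeros((n - 1, n - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = D2[:-1, -1] = new_row[keep]
        D = D2
        nodes = [nodes[k] for k in keep] + [new_node]

    # final trifurcation: closed-form star branch lengths
    (a, b, c) = nodes
    d_ab, d_ac, d_bc = D[0, 1], D[0, 2], D[1, 2]
    la = 0.5 * (d_ab + d_ac - d_bc)
    lb = 0.5 * (d_ab + d_bc - d_ac)
    lc = 0.5 * (d_ac + d_bc - d_ab)
    a.length, b.length = _clip_pair(la, lb)
    c.length = max(lc, 0.0)
    return TreeNode(children=[a, b, c])


def to_newick(tree: TreeNode) -> str:
    """Serialize a tree to a Newick string."""
    buf = io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()


def read_newick(newick: str) -> TreeNode:
    """Parse a Newick string into a tree (raises on malformed input)."""
    try:
        tree = TreeNode.read(io.StringIO(newick), format="newick")
    except Exception as exc:  # skbio raises several parser error types
        raise DomestiscanError(f"malformed Newick string: {exc}") from exc
    if tree.count(tips=True) < 1:
        raise DomestiscanError("Newick string contains no taxa")
    return tree


def tree_splits(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial bipartitions of the tips, orientation-free.

    Each internal edge is reported as the frozenset of the smaller side
    (ties by sorted order), so rooted and unrooted drawings of the same
    topology compare equal.
    """
    tips = frozenset(t.name for t in tree.tips())
    splits = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        other = tips - side
        if len(side) < 2 or len(other) < 2:
            continue
        smaller = min(side, other, key=lambda s: (len(s), tuple(sorted(s))))
        splits.add(smaller)
    return splits


def domain_identity(seq_a: str, seq_b: str, window: tuple[int, int]) -> float:
    """Fraction of identical columns within a half-open alignment window.

    Gap-gap columns are excluded from both numerator and denominator; a
    gap in only one sequence counts as a mismatch.
    """
    start, end = window
    if not (0 <= start < end <= min(len(seq_a), len(seq_b))):
        raise DomestiscanError(f"window {window} invalid for the given sequences")
    a = seq_a[start:end].upper()
    b = seq_b[start:end].upper()
    ident = 0
    total = 0
    for x, y in zip(a, b):
        if x in "-." and y in "-.":
            continue
        total += 1
        ident += x == y
    if total == 0:
        raise DomestiscanError("window contains only gap-gap columns")
    return ident / total
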