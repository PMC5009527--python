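"""Guide-tree construction: UPGMA vs WPGMA, selected by PID discrepancy.

Both methods agglomerate: repeatedly merge the two closest clusters.  They
differ only in how the distance from a cluster ℓ to the freshly merged
cluster k = i ∪ j is updated:

* UPGMA (size-weighted):  d_ℓk = (|C_i|·d_ℓi + |C_j|·d_ℓj) / (|C_i|+|C_j|)
* WPGMA (equal-weighted): d_ℓk = (d_ℓi + d_ℓj) / 2

The two coincide whenever |C_i| = |C_j|.  WPGMA is the better choice for
families whose members share conserved regions but diverge elsewhere
(low σ(PID)): such a cluster behaves like a single meta-sequence, so its
size should not weight the update.  The selection rule is WPGMA iff
σ(PID) < τ (default τ = 11.5 %), UPGMA otherwise.

The pairwise distance fed to the agglomeration is 1 − expected accuracy,
where expected accuracy of a pair is the posterior mass collected by the
best posterior-decoding alignment, normalized by the shorter length.
``1 − PID`` is available as an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .errors import InputError
from .posterior import PosteriorSet
from .seqio import Family

UPGMA = "upgma"
WPGMA = "wpgma"
METHODS = (UPGMA, WPGMA)


@dataclass(frozen=True)
class TreeNode:
    """A node of the guide tree.

    Leaves carry ``index`` (position in the family) and height 0; internal
    nodes carry their two children, the merge height and the cluster size.
    """

    height: float
    size: int
    index: int | None = None
    children: tuple["TreeNode", "TreeNode"] | None = None

    @property
    def is_leaf(self) -> bool:
        return self.index is not None

    def leaf_indices(self) -> list[int]:
        if self.is_leaf:
            return [self.index]
        out = []
        for child in self.children:
            out.extend(child.leaf_indices())
        return out


@dataclass(frozen=True)
class GuideTree:
    root: TreeNode
    ids: tuple[str, ...]

    def to_newick(self) -> str:
        def render(node: TreeNode, parent_height: float) -> str:
            branch = parent_height - node.height
            if node.is_leaf:
                return f"{self.ids[node.index]}:{branch:.6g}"
            inner = ",".join(render(c, node.height) for c in node.children)
            return f"({inner}):{branch:.6g}"

        a, b = self.root.children
        inner = ",".join(render(c, self.root.height) for c in (a, b))
        return f"({inner});"

    def internal_nodes(self) -> list[TreeNode]:
        out = []

        def walk(node: TreeNode) -> None:
            if not node.is_leaf:
                out.append(node)
                for c in node.children:
                    walk(c)

        walk(self.root)
        return out


def expected_accuracy(post: np.ndarray) -> float:
    """Best posterior-decoding alignment mass over min(|x|, |y|).

    The DP maximizes the summed match posteriors over one monotone
    alignment; normalizing by the shorter length bounds the value by 1
    for a well-formed posterior matrix (row/column sums <= 1).
    """
    lx, ly = post.shape
    prev = np.zeros(ly + 1)
    for i in range(1, lx + 1):
        cur = np.zeros(ly + 1)
        row = post[i - 1]
        for j in range(1, ly + 1):
            cur[j] = max(prev[j - 1] + row[j - 1], prev[j], cur[j - 1])
        prev = cur
    return float(prev[ly]) / min(lx, ly)


def distance_matrix(
    posteriors: PosteriorSet, family: Family, *, definition: str = "accuracy"
) -> np.ndarray:
    """Symmetric dissimilarity matrix with zero diagonal.

    ``definition`` is ``"accuracy"`` (1 − expected pairwise accuracy,
    default) — pass a :class:`~pnpalign.similarity.PidStats` based matrix
    directly to :func:`build_tree` for the 1 − PID alternative.
    """
    if definition != "accuracy":
        raise InputError(f"unknown distance definition {definition!r}")
    n = len(family)
    d = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        acc = expected_accuracy(posteriors.get(i, j))
        d[i, j] = d[j, i] = float(np.clip(1.0 - acc, 0.0, 1.0))
    return d


def merge_distance_upgma(d_li: float, d_lj: float, size_i: int, size_j: int) -> float:
    """Size-weighted merge distance."""
    return (size_i * d_li + size_j * d_lj) / (size_i + size_j)


def merge_distance_wpgma(d_li: float, d_lj: float) -> float:
    """Equal-weighted merge distance."""
    return (d_li + d_lj) / 2.0


def _validate_distance_matrix(dist: np.ndarray) -> np.ndarray:
    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    if dist.ndim != 2 or dist.shape != (n, n) or n < 2:
        raise InputError("distance matrix must be square with N >= 2")
    if not np.allclose(dist, dist.T):
        raise InputError("distance matrix must be symmetric")
    if np.any(np.diag(dist) != 0):
        raise InputError("distance matrix diagonal must be exactly 0")
    if np.any(dist < 0):
        raise InputError("distances must be non-negative")
    return dist


def build_tree(dist: np.ndarray, method: str, ids=None) -> GuideTree:
    """Agglomerate a distance matrix into a rooted binary guide tree.

    Merge heights are half the merge distance (the ultrametric
    convention).  When several cluster pairs attain the minimum distance,
    the pair whose merged leaf set has the lexicographically smallest
    (min leaf index, max leaf index) wins, making the tree deterministic.
    """
    if method not in METHODS:
        raise InputError(f"unknown guide-tree method {method!r}")
    dist = _validate_distance_matrix(dist)
    n = dist.shape[0]
    if ids is None:
        ids = tuple(str(i) for i in range(n))
    ids = tuple(ids)
    if len(ids) != n:
        raise InputError("ids must match the distance matrix size")

    nodes: dict[int, TreeNode] = {
        i: TreeNode(height=0.0, size=1, index=i) for i in range(n)
    }
    span: dict[int, tuple[int, int]] = {i: (i, i) for i in range(n)}  # (min, max) leaf
    d: dict[tuple[int, int], float] = {
        (i, j): float(dist[i, j]) for i, j in combinations(range(n), 2)
    }
    next_key = n

    def pair_d(a: int, b: int) -> float:
        return d[(a, b) if a < b else (b, a)]

    while len(nodes) > 1:
        active = sorted(nodes)
        best = None
        for a, b in combinations(active, 2):
            mins = min(span[a][0], span[b][0])
            maxs = max(span[a][1], span[b][1])
            cand = (pair_d(a, b), mins, maxs, a, b)
            if best is None or cand < best:
                best = cand
        dd, _, _, i, j = best
        merged = TreeNode(
            height=dd / 2.0,
            size=nodes[i].size + nodes[j].size,
            children=(nodes[i], nodes[j]),
        )
        k = next_key
        next_key += 1
        for l in active:
            if l in (i, j):
                continue
            if method == UPGMA:
                dk = merge_distance_upgma(
                    pair_d(l, i), pair_d(l, j), nodes[i].size, nodes[j].size
                )
            else:
                dk = merge_distance_wpgma(pair_d(l, i), pair_d(l, j))
            d[(min(l, k), max(l, k))] = dk
        span[k] = (
            min(span[i][0], span[j][0]),
            max(span[i][1], span[j][1]),
        )
        nodes[k] = merged
        del nodes[i], nodes[j]
    return GuideTree(root=nodes[next_key - 1], ids=ids)


def select_tree_method(sd_pid: float, tau: float = 0.115) -> str:
    """WPGMA iff σ(PID) < τ (strict); UPGMA otherwise, including σ = τ."""
    if sd_pid < 0:
        raise InputError("sd_pid must be non-negative")
    return WPGMA if sd_pid < tau else UPGMA
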