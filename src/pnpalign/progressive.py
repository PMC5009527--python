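"""Progressive profile–profile alignment along the guide tree.

Profiles are partial alignments over disjoint subsets of the family.  Two
profiles are aligned column against column by dynamic programming that
maximizes the total column score, where a column pairing (i, j) scores the
*mean* posterior match probability over all cross-sequence pairs that have
a residue in both columns.  The mean (rather than the sum) keeps large
profiles from out-shouting small ones, and no explicit gap penalty is
needed: skipping a column simply forgoes posterior mass.

Tie-breaking in the DP prefers a column match, then consuming a column of
the first profile, then of the second — fixed so output is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvariantError
from .guidetree import GuideTree, TreeNode
from .posterior import PosteriorSet
from .seqio import GAP, Alignment, Family

_MATCH, _GAP_B, _GAP_A = 0, 1, 2  # traceback codes, in preference order


@dataclass
class Profile:
    """An alignment fragment: global sequence indices plus gapped rows."""

    indices: list[int]
    rows: list[str]

    def __post_init__(self) -> None:
        if len({len(r) for r in self.rows}) > 1:
            raise InvariantError("profile rows have unequal lengths")
        if len(self.indices) != len(self.rows):
            raise InvariantError("profile indices and rows disagree")

    @property
    def width(self) -> int:
        return len(self.rows[0])

    def position_map(self, r: int) -> np.ndarray:
        """Column -> 0-based residue position for row r, or -1 at gaps."""
        row = self.rows[r]
        out = np.full(len(row), -1, dtype=np.int64)
        pos = 0
        for c, ch in enumerate(row):
            if ch != GAP:
                out[c] = pos
                pos += 1
        return out


def _column_scores(
    a: Profile, b: Profile, posteriors: PosteriorSet
) -> np.ndarray:
    """Mean cross-pair posterior for every column pairing, shape (Wa, Wb)."""
    total = np.zeros((a.width, b.width))
    count = np.zeros((a.width, b.width))
    for ra, ia in enumerate(a.indices):
        amap = a.position_map(ra)
        amask = amap >= 0
        acols = np.nonzero(amask)[0]
        for rb, ib in enumerate(b.indices):
            post = posteriors.get(ia, ib)
            bmap = b.position_map(rb)
            bcols = np.nonzero(bmap >= 0)[0]
            if len(acols) == 0 or len(bcols) == 0:
                continue
            sub = post[np.ix_(amap[acols], bmap[bcols])]
            total[np.ix_(acols, bcols)] += sub
            count[np.ix_(acols, bcols)] += 1.0
    with np.errstate(invalid="ignore", divide="ignore"):
        score = np.where(count > 0, total / np.maximum(count, 1.0), 0.0)
    return score


def _strip_all_gap_columns(rows: list[str]) -> list[str]:
    if not rows:
        return rows
    keep = [c for c in range(len(rows[0])) if any(r[c] != GAP for r in rows)]
    return ["".join(r[c] for c in keep) for r in rows]


def align_profiles(a: Profile, b: Profile, posteriors: PosteriorSet) -> Profile:
    """Align two profiles, maximizing total mean-posterior column score."""
    if set(a.indices) & set(b.indices):
        raise InvariantError("profiles to align share sequences")
    score = _column_scores(a, b, posteriors)
    wa, wb = a.width, b.width
    dp = np.zeros((wa + 1, wb + 1))
    tb = np.zeros((wa + 1, wb + 1), dtype=np.int8)
    tb[1:, 0] = _GAP_B
    tb[0, 1:] = _GAP_A
    for i in range(1, wa + 1):
        row_dp = dp[i]
        prev_dp = dp[i - 1]
        srow = score[i - 1]
        for j in range(1, wb + 1):
            m = prev_dp[j - 1] + srow[j - 1]
            up = prev_dp[j]
            left = row_dp[j - 1]
            if m >= up and m >= left:
                row_dp[j] = m
                tb[i, j] = _MATCH
            elif up >= left:
                row_dp[j] = up
                tb[i, j] = _GAP_B
            else:
                row_dp[j] = left
                tb[i, j] = _GAP_A
    # traceback
    cols: list[tuple[int, int]] = []  # (a column or -1, b column or -1)
    i, j = wa, wb
    while i > 0 or j > 0:
        move = tb[i, j]
        if move == _MATCH and i > 0 and j > 0:
            cols.append((i - 1, j - 1))
            i, j = i - 1, j - 1
        elif move == _GAP_B and i > 0:
            cols.append((i - 1, -1))
            i -= 1
        else:
            cols.append((-1, j - 1))
            j -= 1
    cols.reverse()
    rows = []
    for r in range(len(a.rows)):
        rows.append("".join(a.rows[r][ca] if ca >= 0 else GAP for ca, _ in cols))
    for r in range(len(b.rows)):
        rows.append("".join(b.rows[r][cb] if cb >= 0 else GAP for _, cb in cols))
    rows = _strip_all_gap_columns(rows)
    return Profile(indices=list(a.indices) + list(b.indices), rows=rows)


def progressive_align(
    tree: GuideTree, family: Family, posteriors: PosteriorSet
) -> Alignment:
    """Post-order traversal: leaves become single-sequence profiles, each
    internal node aligns its children's profiles; the root is the MSA."""
    if sorted(tree.root.leaf_indices()) != list(range(len(family))):
        raise InvariantError("guide tree leaves do not match the family")

    def build(node: TreeNode) -> Profile:
        if node.is_leaf:
            return Profile(
                indices=[node.index], rows=[family[node.index].residues]
            )
        left, right = (build(c) for c in node.children)
        return align_profiles(left, right, posteriors)

    root = build(tree.root)
    order = np.argsort(root.indices)
    rows = [(family[root.indices[k]].id, root.rows[k]) for k in order]
    return Alignment(rows)


def profile_from_alignment(alignment: Alignment, family: Family) -> Profile:
    """Profile over the whole family, rows in family order."""
    index = {seq.id: k for k, seq in enumerate(family)}
    pairs = sorted(alignment.rows, key=lambda r: index[r[0]])
    return Profile(indices=[index[rid] for rid, _ in pairs], rows=[r for _, r in pairs])
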