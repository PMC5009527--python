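"""Alignment quality scores and the accumulated score-difference curve.

SP and TC are the community-standard reference-based scores:

* **SP** (sum-of-pairs): the fraction of residue pairs placed in one
  column by the reference that the test alignment also places in one
  column.
* **TC** (total-column): the fraction of reference columns reproduced
  exactly — all (and only) the reference column's residues share one test
  column.  By default only reference columns carrying residues from at
  least two sequences are scored; ``full_columns=True`` restricts to
  columns where every sequence has a residue.

The accumulated-difference curve is the calibration device for threshold
choices: families are grouped by a statistic (σ(PID)), the mean score
difference Δ between two methods is computed per group, and the running
sum k = Σ_{i<=h} Δ_i is plotted against the group bound h.  The curve
rises at h exactly when the first method wins in group h; the abscissa
where it peaks is the natural threshold between the two methods.
"""

from __future__ import annotations

from .errors import InputError
from .seqio import GAP, Alignment


def _residue_columns(aln: Alignment) -> dict[tuple[str, int], int]:
    """(sequence id, 0-based residue position) -> column index."""
    out = {}
    for rid, row in aln.rows:
        pos = 0
        for c, ch in enumerate(row):
            if ch != GAP:
                out[(rid, pos)] = c
                pos += 1
    return out


def _check_comparable(test: Alignment, ref: Alignment) -> None:
    if sorted(test.ids) != sorted(ref.ids):
        raise InputError("test and reference alignments have different ids")
    t, r = dict(test.degapped()), dict(ref.degapped())
    for rid in t:
        if t[rid] != r[rid]:
            raise InputError(
                f"sequence {rid!r} differs between test and reference"
            )


def _ref_columns(ref: Alignment, full_columns: bool) -> list[list[tuple[str, int]]]:
    """Scored reference columns as lists of (id, residue position)."""
    colmap = _residue_columns(ref)
    by_col: dict[int, list[tuple[str, int]]] = {}
    for key, c in colmap.items():
        by_col.setdefault(c, []).append(key)
    need = ref.nrows if full_columns else 2
    return [sorted(v) for _, v in sorted(by_col.items()) if len(v) >= need]


def sp_score(test: Alignment, ref: Alignment) -> float:
    """Fraction of reference-aligned residue pairs recovered by ``test``."""
    _check_comparable(test, ref)
    test_cols = _residue_columns(test)
    total = 0
    hit = 0
    for col in _ref_columns(ref, full_columns=False):
        for a in range(len(col)):
            for b in range(a + 1, len(col)):
                total += 1
                if test_cols[col[a]] == test_cols[col[b]]:
                    hit += 1
    return hit / total if total else 0.0


def tc_score(test: Alignment, ref: Alignment, *, full_columns: bool = False) -> float:
    """Fraction of scored reference columns reproduced exactly by ``test``."""
    _check_comparable(test, ref)
    test_cols = _residue_columns(test)
    by_test_col: dict[int, list[tuple[str, int]]] = {}
    for key, c in test_cols.items():
        by_test_col.setdefault(c, []).append(key)
    ref_cols = _ref_columns(ref, full_columns)
    if not ref_cols:
        return 0.0
    hit = 0
    for col in ref_cols:
        c = test_cols[col[0]]
        if sorted(by_test_col[c]) == col:
            hit += 1
    return hit / len(ref_cols)


def accumulated_difference(
    groups: dict[float, tuple[float, float]],
) -> list[tuple[float, float]]:
    """Running-sum curve of per-group mean score differences.

    ``groups`` maps the group bound h (e.g. a σ(PID) bin) to the pair of
    mean scores (method A, method B); Δ = A − B per group.  Returns the
    points (h, k = Σ_{i<=h} Δ_i) in increasing h.
    """
    curve = []
    k = 0.0
    for h in sorted(groups):
        a, b = groups[h]
        k += a - b
        curve.append((h, k))
    return curve
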