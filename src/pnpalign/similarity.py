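"""Percent identity (PID) statistics.

The pipeline's two adaptive decisions — which pair-HMM to use, and whether
to align progressively at all — are driven entirely by two numbers computed
here: the family's average pairwise percent identity avg(PID) (its
*similarity*) and the standard deviation of the pairwise PIDs σ(PID) (its
*discrepancy*).  A low σ(PID) flags families that share conserved regions
but diverge elsewhere, because every pair then agrees on roughly the same
identity fraction.

PID of a pair is the identity fraction of one optimal global (Needleman–
Wunsch) alignment under a fixed classical scheme: BLOSUM62, gap open −10,
gap extend −1 (a gap of length k costs 10 + (k − 1)).  This keeps PID
independent of the posterior stage, whose model PID itself selects.  The
denominator convention is configurable:

* ``"aligned"`` (default) — columns where both sequences carry a residue;
* ``"shorter"`` — length of the shorter sequence;
* ``"columns"`` — total alignment columns.

Letters outside the BLOSUM62 alphabet are scored as 'X' during alignment
and never count as identical.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices

from .errors import InputError
from .seqio import Family, Sequence

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
#: letters with a BLOSUM62 row; anything else is treated as unknown
KNOWN_LETTERS = frozenset(str(_BLOSUM62.alphabet)) - {"*"}

DENOMINATORS = ("aligned", "shorter", "columns")


@lru_cache(maxsize=8)
def _aligner(gap_open: float, gap_extend: float) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = _BLOSUM62
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def _sanitize(residues: str) -> str:
    return "".join(c if c in KNOWN_LETTERS else "X" for c in residues)


def pairwise_pid(
    x: Sequence,
    y: Sequence,
    *,
    denominator: str = "aligned",
    gap_open: float = 10.0,
    gap_extend: float = 1.0,
) -> float:
    """Identity fraction of an optimal global alignment of ``x`` and ``y``.

    Symmetric in its arguments and 1.0 for identical sequences (under the
    default denominator).  Deterministic: Biopython enumerates co-optimal
    alignments in a fixed order and the first is used; identity counts may
    differ across co-optimal alignments, a documented limitation.
    """
    if denominator not in DENOMINATORS:
        raise InputError(f"unknown PID denominator {denominator!r}")
    if len(x) == 0 or len(y) == 0:
        raise InputError("PID of an empty sequence is undefined")
    alignment = _aligner(gap_open, gap_extend).align(
        _sanitize(x.residues), _sanitize(y.residues)
    )[0]
    identical = 0
    aligned_cols = 0
    for (xs, xe), (ys, ye) in zip(*alignment.aligned):
        aligned_cols += xe - xs
        for a, b in zip(x.residues[xs:xe], y.residues[ys:ye]):
            if a == b and a in KNOWN_LETTERS:
                identical += 1
    if denominator == "aligned":
        denom = aligned_cols
    elif denominator == "shorter":
        denom = min(len(x), len(y))
    else:
        denom = alignment.shape[1]
    return identical / denom if denom else 0.0


@dataclass(frozen=True)
class PidStats:
    """Pairwise PID matrix plus the family's similarity and discrepancy."""

    pairwise_pids: np.ndarray  # symmetric N x N, diagonal 1
    avg_pid: float  # mean over the N(N-1)/2 unordered pairs
    sd_pid: float  # population SD over the same pairs

    def pair(self, i: int, j: int) -> float:
        return float(self.pairwise_pids[i, j])


def family_pid_stats(family: Family, **pid_kwargs) -> PidStats:
    """avg(PID) and σ(PID) over all unordered pairs of the family.

    σ(PID) is the population standard deviation: the family's pair PIDs are
    the complete population, not a sample.
    """
    n = len(family)
    mat = np.eye(n)
    values = []
    for i, j in combinations(range(n), 2):
        pid = pairwise_pid(family[i], family[j], **pid_kwargs)
        mat[i, j] = mat[j, i] = pid
        values.append(pid)
    arr = np.asarray(values)
    return PidStats(mat, float(arr.mean()), float(arr.std()))
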