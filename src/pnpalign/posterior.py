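"""Posterior alignment probabilities and the consistency transformation.

For every ordered residue pair (x_i, y_j) of two sequences, the posterior
Pr(x_i, y_j) is the probability, under a pair-HMM and conditional on the
two sequences, that x_i and y_j are emitted together from a Match state —
i.e. that the pair sits in the same column, marginalized over all pairwise
alignments.  It is computed with the forward–backward algorithm in log
space (log-sum-exp), so arbitrarily long inputs cannot underflow.

The consistency transformation then re-estimates each pairwise matrix by
relaying through every third sequence z:

    P'_xy = (1/N) * sum_z  P_xz · P_zy        (P_xx = identity)

which rewards residue pairs whose alignment is corroborated by the rest of
the family.  Entries below a sparsity cutoff are dropped (set to zero)
after each stage; matrices are kept dense, the cutoff only zeroes noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .errors import InputError
from .hmm import MATCH, PairHmm
from .seqio import Family, Sequence

_NEG_INF = float("-inf")

DEFAULT_SPARSITY_CUTOFF = 0.01


def _log(a: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return np.log(a)


def _forward(
    hmm: PairHmm, lex: np.ndarray, ley: np.ndarray, leM: np.ndarray
) -> tuple[np.ndarray, float]:
    """Log-space forward matrices, shape (n_states, lx+1, ly+1), and log Z.

    ``f[s, i, j]`` is the log probability of emitting the prefixes x[1..i]
    and y[1..j] and currently being in state s.  The start distribution is
    applied at the three cells a first emission can reach.
    """
    n = hmm.n_states
    lx, ly = len(lex), len(ley)
    li, le = _log(hmm.init), _log(hmm.end)
    lt = _log(hmm.trans)
    kinds = hmm.kinds

    f = np.full((n, lx + 1, ly + 1), _NEG_INF)
    for i in range(lx + 1):
        for j in range(ly + 1):
            if i == 0 and j == 0:
                continue
            for t in range(n):
                k = kinds[t]
                if k == MATCH and i >= 1 and j >= 1:
                    v = np.logaddexp.reduce(f[:, i - 1, j - 1] + lt[:, t])
                    if i == 1 and j == 1:
                        v = np.logaddexp(v, li[t])
                    f[t, i, j] = leM[i - 1, j - 1] + v
                elif k == "X" and i >= 1:
                    v = np.logaddexp.reduce(f[:, i - 1, j] + lt[:, t])
                    if i == 1 and j == 0:
                        v = np.logaddexp(v, li[t])
                    f[t, i, j] = lex[i - 1] + v
                elif k == "Y" and j >= 1:
                    v = np.logaddexp.reduce(f[:, i, j - 1] + lt[:, t])
                    if i == 0 and j == 1:
                        v = np.logaddexp(v, li[t])
                    f[t, i, j] = ley[j - 1] + v
    log_z = float(np.logaddexp.reduce(f[:, lx, ly] + le))
    return f, log_z


def _backward(
    hmm: PairHmm, lex: np.ndarray, ley: np.ndarray, leM: np.ndarray
) -> np.ndarray:
    """Log-space backward matrices, same shape as the forward matrices.

    ``b[s, i, j]`` is the log probability of emitting the remaining
    suffixes and then terminating, given the path is in state s having
    just produced position (i, j).
    """
    n = hmm.n_states
    lx, ly = len(lex), len(ley)
    le = _log(hmm.end)
    lt = _log(hmm.trans)
    kinds = hmm.kinds

    b = np.full((n, lx + 1, ly + 1), _NEG_INF)
    b[:, lx, ly] = le
    for i in range(lx, -1, -1):
        for j in range(ly, -1, -1):
            if i == lx and j == ly:
                continue
            # d[t]: value of stepping into target state t from (i, j)
            d = np.full(n, _NEG_INF)
            for t in range(n):
                k = kinds[t]
                if k == MATCH and i < lx and j < ly:
                    d[t] = leM[i, j] + b[t, i + 1, j + 1]
                elif k == "X" and i < lx:
                    d[t] = lex[i] + b[t, i + 1, j]
                elif k == "Y" and j < ly:
                    d[t] = ley[j] + b[t, i, j + 1]
            b[:, i, j] = np.logaddexp.reduce(lt + d[None, :], axis=1)
    return b


def forward_backward(
    x: Sequence,
    y: Sequence,
    hmm: PairHmm,
    *,
    cutoff: float = DEFAULT_SPARSITY_CUTOFF,
) -> np.ndarray:
    """Posterior match probabilities Pr(x_i, y_j), shape (|x|, |y|).

    Entry (i, j) (0-based) is the probability that residues x_{i+1} and
    y_{j+1} occupy the same alignment column.  Entries below ``cutoff`` are
    zeroed.  Row sums and column sums never exceed 1 (+ float slack): the
    events "x_i pairs with y_j" are mutually exclusive along each axis.
    """
    if len(x) == 0 or len(y) == 0:
        raise InputError("cannot compute posteriors for an empty sequence")
    xc, yc = hmm.encode(x.residues), hmm.encode(y.residues)
    lex = _log(hmm.single_emission(xc))
    ley = _log(hmm.single_emission(yc))
    leM = _log(hmm.pair_emission(xc, yc))
    f, log_z = _forward(hmm, lex, ley, leM)
    b = _backward(hmm, lex, ley, leM)
    post = np.zeros((len(x), len(y)))
    for m in hmm.state_indices(MATCH):
        post += np.exp(f[m, 1:, 1:] + b[m, 1:, 1:] - log_z)
    post = np.clip(post, 0.0, 1.0)
    if cutoff > 0:
        post[post < cutoff] = 0.0
    return post


def combine_models(matrices: list[np.ndarray], weights=None) -> np.ndarray:
    """Entry-wise convex combination of posterior matrices."""
    if not matrices:
        raise InputError("no matrices to combine")
    shapes = {m.shape for m in matrices}
    if len(shapes) > 1:
        raise InputError(f"posterior matrix dimension mismatch: {sorted(shapes)}")
    if weights is None:
        weights = np.full(len(matrices), 1 / len(matrices))
    weights = np.asarray(weights, dtype=float)
    if len(weights) != len(matrices) or not np.isclose(weights.sum(), 1.0):
        raise InputError("weights must match the matrices and sum to 1")
    out = np.zeros(matrices[0].shape)
    for w, m in zip(weights, matrices):
        out += w * m
    return out


@dataclass
class PosteriorSet:
    """Posterior matrices for every unordered pair of a family.

    Matrices are stored once per pair under the key ``(i, j)`` with
    ``i < j``; :meth:`get` transposes transparently for the reverse order.
    """

    n: int
    matrices: dict[tuple[int, int], np.ndarray]

    def __post_init__(self) -> None:
        expected = {(i, j) for i, j in combinations(range(self.n), 2)}
        if set(self.matrices) != expected:
            raise InputError("PosteriorSet must cover every pair exactly once")

    def get(self, i: int, j: int) -> np.ndarray:
        if i == j:
            raise InputError("no posterior matrix for a sequence against itself")
        return self.matrices[(i, j)] if i < j else self.matrices[(j, i)].T

    def pairs(self):
        return sorted(self.matrices)


def compute_posteriors(
    family: Family,
    models: list[PairHmm],
    *,
    weights=None,
    cutoff: float = DEFAULT_SPARSITY_CUTOFF,
) -> PosteriorSet:
    """Forward–backward posteriors for all pairs, averaged over ``models``.

    Each model's posterior matrix is computed exactly; the convex
    combination is formed first and the sparsity cutoff applied once to the
    combined matrix.
    """
    mats = {}
    for i, j in combinations(range(len(family)), 2):
        per_model = [
            forward_backward(family[i], family[j], m, cutoff=0.0) for m in models
        ]
        combined = combine_models(per_model, weights)
        if cutoff > 0:
            combined[combined < cutoff] = 0.0
        mats[(i, j)] = combined
    return PosteriorSet(len(family), mats)


def consistency_transform(
    posteriors: PosteriorSet,
    rounds: int = 2,
    *,
    cutoff: float = DEFAULT_SPARSITY_CUTOFF,
) -> PosteriorSet:
    """Relay each pairwise matrix through all sequences, ``rounds`` times.

    One round replaces P_xy by (1/N) Σ_z P_xz P_zy with P_xx the identity,
    so the z = x and z = y terms each contribute P_xy itself.  The sparsity
    cutoff is re-applied after every round.  ``rounds = 0`` is the identity.
    """
    if rounds < 0:
        raise InputError("rounds must be >= 0")
    n = posteriors.n
    current = posteriors
    for _ in range(rounds):
        new = {}
        for i, j in current.pairs():
            acc = 2.0 * current.get(i, j)
            for z in range(n):
                if z == i or z == j:
                    continue
                acc = acc + current.get(i, z) @ current.get(z, j)
            mat = acc / n
            if cutoff > 0:
                mat[mat < cutoff] = 0.0
            new[(i, j)] = mat
        current = PosteriorSet(n, new)
    return current
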