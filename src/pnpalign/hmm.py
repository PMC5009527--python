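"""Pair hidden Markov models for posterior alignment probabilities.

A :class:`PairHmm` has one Match state (emitting a residue pair) and one or
more insert states per sequence (emitting a single residue).  Two model
families are provided:

* ``global_model()`` — the classical 3-state global pair-HMM (Match plus
  one insert tier per sequence), appropriate when the input family's
  average identity is high and sequences are alignable end to end.
* ``local_models()`` — 5-state variants with a second, long-gap insert
  tier.  Start/end probability mass is placed on the long-gap tier, so an
  alignment may enter and leave long unaligned flanks almost freely: this
  models distant homologs that share only local domains or motifs.

The paper this tool family descends from prints no numeric parameters, so
the defaults here are the package's own, fully overridable via a flat
key-value parameter file (:func:`save_params` / :func:`load_params`).

Match emissions are derived from BLOSUM62 by inverting its log-odds
construction: BLOSUM62 scores are (rounded) ``2·log2(p_ab / f_a f_b)`` in
half-bits, so ``p_ab ∝ f_a f_b · 2^(s_ab/2)``.  Requiring the joint
distribution's marginals to equal the backgrounds themselves reduces to a
single linear solve (see :func:`blosum62_pair_distribution`); the
marginals also serve as the insert-state emission distribution.  Letters
outside the 20 standard amino acids emit uniformly (1/20) and pair as if
independent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.Align import substitution_matrices

from .errors import InputError

PARAMS_FORMAT_VERSION = 1

#: the 20 standard amino acids, in BLOSUM row order
AA20 = "ARNDCQEGHILKMFPSTWYV"
_AA_INDEX = {c: i for i, c in enumerate(AA20)}

MATCH, INSERT_X, INSERT_Y = "M", "X", "Y"


def blosum62_pair_distribution() -> tuple[np.ndarray, np.ndarray]:
    """Joint match distribution ``p[a, b]`` and background ``f[a]`` from BLOSUM62.

    BLOSUM62 scores are (rounded) half-bit log-odds, s_ab = 2·log2(p_ab /
    f_a f_b), so p_ab = f_a f_b K_ab with K = 2^(S/2).  Requiring the
    marginals of p to equal f itself forces Σ_b K_ab f_b to be constant in
    a, i.e. f ∝ K⁻¹·1 — a linear solve, no iteration.  The solution is
    strictly positive for BLOSUM62 and reproduces the familiar amino-acid
    background frequencies (A ≈ 8 %, W ≈ 1 %, ...).

    Returns a symmetric 20x20 distribution summing to 1 and its marginal.
    """
    m = substitution_matrices.load("BLOSUM62")
    scores = np.array([[m[a, b] for b in AA20] for a in AA20], dtype=float)
    kernel = np.exp2(scores / 2.0)
    f = np.linalg.solve(kernel, np.ones(20))
    if np.any(f <= 0):  # cannot happen for BLOSUM62; guards future matrices
        f = np.abs(f)
    f /= f.sum()
    p = np.outer(f, f) * kernel
    p /= p.sum()
    return p, f


@dataclass(frozen=True)
class PairHmm:
    """A pair-HMM over two sequences.

    ``kinds[s]`` is 'M' (emits a residue pair), 'X' (emits from the first
    sequence) or 'Y' (emits from the second).  ``trans[s, t]`` are
    transition probabilities; together with the explicit end probability
    ``end[s]`` each row sums to 1.  ``init`` is the start distribution.
    ``match_emit`` is the 20x20 joint residue-pair distribution for Match;
    ``single_emit`` the background distribution for insert states.
    """

    name: str
    kinds: str
    init: np.ndarray
    trans: np.ndarray
    end: np.ndarray
    match_emit: np.ndarray
    single_emit: np.ndarray
    local: bool = False

    def __post_init__(self) -> None:
        n = len(self.kinds)
        if self.trans.shape != (n, n) or len(self.init) != n or len(self.end) != n:
            raise InputError("pair-HMM parameter shapes are inconsistent")
        if not np.isclose(self.init.sum(), 1.0, atol=1e-9):
            raise InputError("pair-HMM start distribution does not sum to 1")
        row_sums = self.trans.sum(axis=1) + self.end
        if not np.allclose(row_sums, 1.0, atol=1e-9):
            raise InputError("pair-HMM transition rows (incl. end) must sum to 1")
        for arr in (self.init, self.trans, self.end, self.match_emit, self.single_emit):
            if np.any(arr < 0) or np.any(arr > 1):
                raise InputError("pair-HMM probabilities must lie in [0, 1]")
        if not np.allclose(self.match_emit, self.match_emit.T, atol=1e-12):
            raise InputError("match emission table must be symmetric")

    @property
    def n_states(self) -> int:
        return len(self.kinds)

    def state_indices(self, kind: str) -> list[int]:
        return [s for s, k in enumerate(self.kinds) if k == kind]

    # -- emission lookups -------------------------------------------------

    def encode(self, residues: str) -> np.ndarray:
        """Residues to indices into AA20; unknown letters become -1."""
        return np.array([_AA_INDEX.get(c, -1) for c in residues], dtype=np.int64)

    def pair_emission(self, xc: np.ndarray, yc: np.ndarray) -> np.ndarray:
        """Match emission matrix e(x_i, y_j), shape (len x, len y).

        Unknown letters emit as independent uniform draws.
        """
        qx = np.where(xc >= 0, self.single_emit[np.maximum(xc, 0)], 1 / 20)
        qy = np.where(yc >= 0, self.single_emit[np.maximum(yc, 0)], 1 / 20)
        out = np.outer(qx, qy)
        kx, ky = xc >= 0, yc >= 0
        both = np.ix_(np.nonzero(kx)[0], np.nonzero(ky)[0])
        out[both] = self.match_emit[np.ix_(xc[kx], yc[ky])]
        return out

    def single_emission(self, codes: np.ndarray) -> np.ndarray:
        return np.where(codes >= 0, self.single_emit[np.maximum(codes, 0)], 1 / 20)


def _shared_emissions() -> tuple[np.ndarray, np.ndarray]:
    if not hasattr(_shared_emissions, "_cache"):
        _shared_emissions._cache = blosum62_pair_distribution()
    return _shared_emissions._cache


def global_model(delta: float = 0.02, epsilon: float = 0.4, tau: float = 0.02) -> PairHmm:
    """3-state global pair-HMM (Match, InsertX, InsertY).

    ``delta`` is the gap-open probability per insert state, ``epsilon`` the
    gap-extension probability, ``tau`` the per-state end probability.
    """
    p, f = _shared_emissions()
    trans = np.array(
        [
            [1 - 2 * delta - tau, delta, delta],
            [1 - epsilon - tau, epsilon, 0.0],
            [1 - epsilon - tau, 0.0, epsilon],
        ]
    )
    return PairHmm(
        name="global3",
        kinds=MATCH + INSERT_X + INSERT_Y,
        init=np.array([1 - 2 * delta, delta, delta]),
        trans=trans,
        end=np.full(3, tau),
        match_emit=p,
        single_emit=f,
        local=False,
    )


def local_model(
    name: str = "local5",
    delta1: float = 0.012,
    epsilon1: float = 0.4,
    delta2: float = 0.01,
    epsilon2: float = 0.9,
    tau: float = 0.02,
) -> PairHmm:
    """5-state pair-HMM with a long-gap insert tier and free-ish flanks.

    Tier 1 models ordinary short indels; tier 2 (open ``delta2``, extend
    ``epsilon2`` close to 1) models long unalignable stretches.  The start
    distribution places half its mass on tier-2 inserts so alignments can
    begin inside a divergent flank, giving local alignment semantics.
    """
    p, f = _shared_emissions()
    d = 2 * delta1 + 2 * delta2
    trans = np.array(
        [
            [1 - d - tau, delta1, delta1, delta2, delta2],
            [1 - epsilon1 - tau, epsilon1, 0, 0, 0],
            [1 - epsilon1 - tau, 0, epsilon1, 0, 0],
            [1 - epsilon2 - tau, 0, 0, epsilon2, 0],
            [1 - epsilon2 - tau, 0, 0, 0, epsilon2],
        ]
    )
    return PairHmm(
        name=name,
        kinds=MATCH + INSERT_X + INSERT_Y + INSERT_X + INSERT_Y,
        init=np.array([0.4, 0.05, 0.05, 0.25, 0.25]),
        trans=trans,
        end=np.full(5, tau),
        match_emit=p,
        single_emit=f,
        local=True,
    )


def local_models() -> list[PairHmm]:
    """Default local model set: two long-gap variants (ε₂ = 0.9 and 0.95).

    How many local models the ancestor tools combine is not published; two
    variants spanning moderate and very long divergent stretches is this
    package's documented default.
    """
    return [
        local_model(name="local5a", epsilon2=0.9),
        local_model(name="local5b", epsilon2=0.95),
    ]


# -- flat key-value parameter files ---------------------------------------


def save_params(hmm: PairHmm, path: str) -> None:
    """Write a model as versioned flat ``key = value`` text."""
    with open(path, "w") as fh:
        fh.write(f"format_version = {PARAMS_FORMAT_VERSION}\n")
        fh.write(f"name = {hmm.name}\n")
        fh.write(f"kinds = {hmm.kinds}\n")
        fh.write(f"local = {int(hmm.local)}\n")
        fh.write(f"alphabet = {AA20}\n")
        for s in range(hmm.n_states):
            fh.write(f"init {s} = {float(hmm.init[s])!r}\n")
            fh.write(f"end {s} = {float(hmm.end[s])!r}\n")
        for s in range(hmm.n_states):
            for t in range(hmm.n_states):
                if hmm.trans[s, t]:
                    fh.write(f"trans {s} {t} = {float(hmm.trans[s, t])!r}\n")
        for a in range(20):
            fh.write(f"emit_single {AA20[a]} = {float(hmm.single_emit[a])!r}\n")
        for a in range(20):
            for b in range(a, 20):
                fh.write(
                    f"emit_match {AA20[a]} {AA20[b]} = {float(hmm.match_emit[a, b])!r}\n"
                )


def load_params(path: str) -> PairHmm:
    """Read a model written by :func:`save_params`."""
    entries: dict[tuple[str, ...], str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise InputError(f"{path}: line {lineno}: expected 'key = value'")
            key, _, value = line.partition("=")
            entries[tuple(key.split())] = value.strip()
    try:
        if int(entries[("format_version",)]) != PARAMS_FORMAT_VERSION:
            raise InputError(f"{path}: unsupported parameter file version")
        kinds = entries[("kinds",)]
        n = len(kinds)
        init = np.array([float(entries[("init", str(s))]) for s in range(n)])
        end = np.array([float(entries[("end", str(s))]) for s in range(n)])
        trans = np.zeros((n, n))
        for s in range(n):
            for t in range(n):
                if ("trans", str(s), str(t)) in entries:
                    trans[s, t] = float(entries[("trans", str(s), str(t))])
        single = np.array([float(entries[("emit_single", c)]) for c in AA20])
        match = np.zeros((20, 20))
        for a in range(20):
            for b in range(a, 20):
                v = float(entries[("emit_match", AA20[a], AA20[b])])
                match[a, b] = match[b, a] = v
    except KeyError as exc:
        raise InputError(f"{path}: missing parameter entry {exc}") from exc
    return PairHmm(
        name=entries.get(("name",), "custom"),
        kinds=kinds,
        init=init,
        trans=trans,
        end=end,
        match_emit=match,
        single_emit=single,
        local=bool(int(entries.get(("local",), "0"))),
    )


def select_hmm(avg_pid: float, *, global_threshold: float = 0.40) -> list[PairHmm]:
    """Model set for a family with the given average PID.

    High-identity families (``avg_pid >= global_threshold``; the boundary
    itself takes the global branch) get the single global model; everything
    else gets the local model set, whose posteriors are averaged.
    """
    if not 0.0 <= avg_pid <= 1.0:
        raise InputError(f"avg_pid must be a fraction, got {avg_pid}")
    if avg_pid >= global_threshold:
        return [global_model()]
    return local_models()
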