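"""Iterative refinement by random bipartition and re-alignment.

Each iteration splits the current alignment's sequences into two random
groups (each sequence independently with probability 1/2; splits that
leave a group empty are redrawn without consuming an iteration), degaps
columns that became all-gap within a group, re-aligns the two group
profiles, and keeps the result iff the objective strictly increases.

The objective is the total posterior mass the alignment realizes: the sum
over all sequence pairs and columns of Pr(x_i, y_j) for residues sharing a
column.  Refinement stops after 2N consecutive non-improving iterations,
or after 4N iterations in total, whichever comes first (N = number of
sequences).  Given the same seed the procedure is bit-for-bit
reproducible.
"""

from __future__ import annotations

import numpy as np

from .errors import InputError
from .posterior import PosteriorSet
from .progressive import Profile, align_profiles, profile_from_alignment
from .seqio import GAP, Alignment, Family


def objective(alignment: Alignment, posteriors: PosteriorSet, family: Family) -> float:
    """Sum of pairwise posteriors over residue pairs sharing a column."""
    prof = profile_from_alignment(alignment, family)
    maps = [prof.position_map(r) for r in range(len(prof.rows))]
    total = 0.0
    n = len(prof.indices)
    for a in range(n):
        for b in range(a + 1, n):
            post = posteriors.get(prof.indices[a], prof.indices[b])
            both = (maps[a] >= 0) & (maps[b] >= 0)
            if np.any(both):
                total += float(post[maps[a][both], maps[b][both]].sum())
    return total


def _subprofile(prof: Profile, members: np.ndarray) -> Profile:
    rows = [prof.rows[r] for r in np.nonzero(members)[0]]
    keep = [c for c in range(len(rows[0])) if any(r[c] != GAP for r in rows)]
    rows = ["".join(r[c] for c in keep) for r in rows]
    return Profile(
        indices=[prof.indices[r] for r in np.nonzero(members)[0]], rows=rows
    )


def refine(
    alignment: Alignment,
    posteriors: PosteriorSet,
    family: Family,
    seed: int = 0,
) -> Alignment:
    """Refine an alignment; returns one with objective >= the input's.

    The returned alignment's metadata records the iteration count and seed.
    """
    n = len(family)
    if n < 2:
        raise InputError("refinement needs at least two sequences")
    rng = np.random.default_rng(seed)
    best = alignment
    best_obj = objective(alignment, posteriors, family)
    iterations = 0
    stall = 0
    max_iter, max_stall = 4 * n, 2 * n
    while iterations < max_iter and stall < max_stall:
        while True:
            mask = rng.random(n) < 0.5
            if 0 < mask.sum() < n:  # degenerate splits are redrawn for free
                break
        prof = profile_from_alignment(best, family)
        realigned = align_profiles(
            _subprofile(prof, mask), _subprofile(prof, ~mask), posteriors
        )
        order = np.argsort(realigned.indices)
        candidate = Alignment(
            [(family[realigned.indices[k]].id, realigned.rows[k]) for k in order]
        )
        iterations += 1
        cand_obj = objective(candidate, posteriors, family)
        if cand_obj > best_obj:
            best, best_obj = candidate, cand_obj
            stall = 0
        else:
            stall += 1
    out = Alignment(list(best.rows), metadata=dict(alignment.metadata))
    out.metadata.update(refine_iterations=iterations, refine_seed=seed)
    return out
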