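"""Pipeline orchestration: PID statistics -> posteriors -> strategy -> MSA.

The full algorithm, given a family of N >= 2 sequences:

1. Compute pairwise PIDs, avg(PID) and σ(PID).
2. Pick the pair-HMM set from avg(PID) (global model when similarity is
   high, local models otherwise) and run forward–backward on every pair.
3. Apply the consistency transformation to the posterior matrices.
4. Route on avg(PID):
   * below the anneal threshold (default 18 %) — distantly related:
     non-progressive sequence annealing on the sorted residue pairs;
   * otherwise — normally related: build the distance matrix, choose
     WPGMA iff σ(PID) < τ (default 11.5 %) else UPGMA, and align
     progressively along the guide tree.
5. Iterative refinement by random bipartition (2N/4N stopping rule),
   applied to either branch's output unless disabled.

Every stage re-checks that degapping the alignment reproduces the input.
The returned alignment carries run metadata (strategy, realized
statistics, thresholds, seed) in ``Alignment.metadata``.
"""

from __future__ import annotations

import enum
import logging
import time

from . import annealing, guidetree, hmm, posterior, progressive, refine, similarity
from .config import PipelineConfig
from .seqio import Alignment, Family, check_degap_identity

logger = logging.getLogger("pnpalign")


class Strategy(enum.Enum):
    ANNEAL = "anneal"
    PROGRESSIVE_WPGMA = "wpgma"
    PROGRESSIVE_UPGMA = "upgma"


def select_strategy(stats: similarity.PidStats, config: PipelineConfig) -> Strategy:
    """Route a family by its realized similarity statistics.

    Annealing iff avg(PID) < anneal threshold (strict); otherwise WPGMA
    iff σ(PID) < τ (strict), else UPGMA.
    """
    if stats.avg_pid < config.anneal_threshold:
        return Strategy.ANNEAL
    if stats.sd_pid < config.tree_sd_threshold:
        return Strategy.PROGRESSIVE_WPGMA
    return Strategy.PROGRESSIVE_UPGMA


def _models(avg_pid: float, config: PipelineConfig) -> list[hmm.PairHmm]:
    if config.hmm_params_file:
        return [hmm.load_params(config.hmm_params_file)]
    return hmm.select_hmm(avg_pid, global_threshold=config.hmm_global_threshold)


def run_pipeline(
    family: Family,
    config: PipelineConfig | None = None,
    force_strategy: Strategy | None = None,
) -> Alignment:
    """Run the full adaptive alignment pipeline on a family."""
    config = config or PipelineConfig()
    t0 = time.perf_counter()

    stats = similarity.family_pid_stats(
        family,
        denominator=config.pid_denominator,
        gap_open=config.pid_gap_open,
        gap_extend=config.pid_gap_extend,
    )
    logger.info(
        "similarity: avg(PID)=%.4f sd(PID)=%.4f over %d pairs",
        stats.avg_pid, stats.sd_pid, len(family) * (len(family) - 1) // 2,
    )

    models = _models(stats.avg_pid, config)
    logger.info("pair-HMM set: %s", [m.name for m in models])
    posteriors = posterior.compute_posteriors(
        family, models, cutoff=config.sparsity_cutoff
    )
    posteriors = posterior.consistency_transform(
        posteriors, rounds=config.consistency_rounds, cutoff=config.sparsity_cutoff
    )

    strategy = force_strategy or select_strategy(stats, config)
    logger.info("strategy: %s", strategy.value)
    if strategy is Strategy.ANNEAL:
        alignment = annealing.anneal(family, posteriors, config.sparsity_cutoff)
    else:
        dist = guidetree.distance_matrix(posteriors, family)
        method = (
            guidetree.WPGMA
            if strategy is Strategy.PROGRESSIVE_WPGMA
            else guidetree.UPGMA
        )
        tree = guidetree.build_tree(dist, method, ids=family.ids)
        alignment = progressive.progressive_align(tree, family, posteriors)
        alignment.metadata["guide_tree"] = tree.to_newick()
    check_degap_identity(alignment, family)

    if config.refine:
        alignment = refine.refine(alignment, posteriors, family, seed=config.seed)
        check_degap_identity(alignment, family)

    alignment.metadata.update(
        strategy=strategy.value,
        avg_pid=round(stats.avg_pid, 6),
        sd_pid=round(stats.sd_pid, 6),
        anneal_threshold=config.anneal_threshold,
        tree_sd_threshold=config.tree_sd_threshold,
        models=",".join(m.name for m in models),
        seed=config.seed,
    )
    logger.info("pipeline finished in %.2fs", time.perf_counter() - t0)
    return alignment
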