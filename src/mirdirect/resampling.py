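"""Bootstrap resampling of expression samples and rank aggregation.

Matched expression studies rarely provide more than a few dozen samples, so
a single estimate of a p×p association matrix is noisy.  The bootstrap
draws ⌈rate·n⌉ sample columns with replacement, re-estimates the network on
each replicate, and fuses the replicate networks by the inverse rank
product.  Defaults follow the study conditions: 100 iterations at a 95%
sampling rate.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .data_model import ExpressionMatrix
from .estimators import ESTIMATORS
from .rank_ensemble import AggregatedScores, inverse_rank_product, to_ranks

logger = logging.getLogger(__name__)

_MAX_REDRAWS = 10


@dataclass
class BootstrapConfig:
    iterations: int = 100
    sampling_rate: float = 0.95
    seed: int = 0
    with_replacement: bool = True

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if not 0.0 < self.sampling_rate <= 1.0:
            raise ValueError("sampling_rate must lie in (0, 1]")


def resample(
    x: ExpressionMatrix, cfg: BootstrapConfig, iteration: int
) -> ExpressionMatrix:
    """Draw the ``iteration``-th bootstrap replicate of the sample columns.

    ⌈rate·n⌉ columns are drawn uniformly (with replacement by default).
    The replicate is a deterministic function of (seed, iteration), so
    replicates can be recomputed independently and in any order.  Duplicate
    sample ids get a ``#k`` suffix.  A replicate that produces a constant
    feature row is redrawn (bounded retries).
    """
    if not 0 <= iteration < cfg.iterations:
        raise ValueError(f"iteration {iteration} outside [0, {cfg.iterations})")
    n = x.n_samples
    m = int(np.ceil(cfg.sampling_rate * n))
    rng = np.random.default_rng([cfg.seed, iteration])
    for attempt in range(_MAX_REDRAWS):
        if cfg.with_replacement:
            cols = np.sort(rng.integers(0, n, size=m))
        else:
            cols = np.sort(rng.choice(n, size=m, replace=False))
        values = x.values[:, cols]
        spread = values.max(axis=1) - values.min(axis=1)
        if (spread > 1e-12).all():
            break
        logger.warning(
            "bootstrap replicate %d produced a constant feature row; redrawing "
            "(attempt %d)", iteration, attempt + 1,
        )
    else:
        raise RuntimeError(
            f"bootstrap replicate {iteration} still has constant feature rows "
            f"after {_MAX_REDRAWS} redraws"
        )
    seen: dict[str, int] = {}
    sample_ids = []
    for c in cols:
        sid = x.sample_ids[c]
        k = seen.get(sid, 0)
        seen[sid] = k + 1
        sample_ids.append(sid if k == 0 else f"{sid}#{k}")
    return ExpressionMatrix(values, x.feature_ids, x.feature_kind, sample_ids)


def bootstrap_estimate(
    x: ExpressionMatrix,
    estimator: str,
    cfg: BootstrapConfig,
    estimator_cfg=None,
    signed: bool = False,
) -> AggregatedScores:
    """Fit an estimator on every bootstrap replicate and fuse the rankings.

    ``estimator`` is one of ``corpcor``, ``space``, ``mind``, ``pearson``.
    Each replicate's score matrix is ranked on the bipartite miRNA×mRNA
    block and the rank matrices are combined by the inverse rank product.
    Replicates whose fit fails are skipped with a warning; the aggregate is
    fully deterministic given the config seed.
    """
    if estimator not in ESTIMATORS:
        raise ValueError(
            f"unknown estimator '{estimator}'; choose from {sorted(ESTIMATORS)}"
        )
    fit = ESTIMATORS[estimator]
    mirna_ids, mrna_ids = x.mirna_ids, x.mrna_ids
    rank_matrices = []
    failures = 0
    for it in range(cfg.iterations):
        replicate = resample(x, cfg, it)
        try:
            scores = fit(replicate, estimator_cfg)
        except Exception as exc:  # noqa: BLE001 — a bad replicate is recoverable
            failures += 1
            warnings.warn(
                f"bootstrap replicate {it} failed for {estimator}: {exc}",
                RuntimeWarning,
            )
            continue
        rank_matrices.append(to_ranks(scores, mirna_ids, mrna_ids, signed=signed))
        logger.debug("bootstrap %s: replicate %d/%d done", estimator, it + 1,
                     cfg.iterations)
    if not rank_matrices:
        raise RuntimeError(f"all {cfg.iterations} bootstrap replicates failed")
    out = inverse_rank_product(rank_matrices)
    out.metadata.update({
        "estimator": estimator,
        "bootstrap_iterations": cfg.iterations,
        "sampling_rate": cfg.sampling_rate,
        "seed": cfg.seed,
        "with_replacement": cfg.with_replacement,
        "failed_replicates": failures,
    })
    logger.info(
        "bootstrap %s: aggregated %d/%d replicates", estimator,
        len(rank_matrices), cfg.iterations,
    )
    return out
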