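"""Monte Carlo realization of group sequential two-arm Poisson trials.

Stage totals are drawn directly as ``Y_jk ~ Po(n lambda_j)`` — they are
sufficient for the stage, so simulating individual subject counts would be
distributionally identical and only slower.  The engine determines the test
statistic: the cumulative count difference for exact designs, the Wald
statistic from cumulative rate estimates for normal designs.  Stopping rules
are applied with the boundary conventions of the design: reject when
``T_k >= r_k``, accept when ``T_k < a_k``, continue otherwise.
"""

from __future__ import annotations

import logging
import math
from typing import Tuple

import numpy as np

from .types import (
    EmpiricalOperatingCharacteristics,
    GroupSequentialDesign,
    PoissonRates,
    TrialRealization,
)

logger = logging.getLogger(__name__)

__all__ = ["simulate_trial", "empirical_error_rates"]


def _simulate_batch(
    design: GroupSequentialDesign, rates: PoissonRates, reps: int, rng: np.random.Generator
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized simulation; returns (stopped_at, rejected, y1, y2).

    ``stopped_at`` is 1-based; ``y1``/``y2`` hold the per-stage arm totals of
    every replicate (stages after stopping are drawn but unused, keeping the
    draw count, and hence the stream, independent of the stopping pattern).
    """
    K, n = design.K, design.n
    y1 = rng.poisson(n * rates.lambda1, size=(reps, K))
    y2 = rng.poisson(n * rates.lambda2, size=(reps, K))
    c1 = np.cumsum(y1, axis=1)
    c2 = np.cumsum(y2, axis=1)
    if design.engine == "exact":
        stat = (c1 - c2).astype(float)
    else:
        kn = n * np.arange(1, K + 1)
        lam1 = c1 / kn
        lam2 = c2 / kn
        tot = lam1 + lam2
        with np.errstate(divide="ignore", invalid="ignore"):
            stat = (lam1 - lam2) * np.sqrt(kn / tot)
        # no events on either arm: the Wald statistic is undefined; the
        # decision rule falls to the accept branch
        undefined = tot == 0
        if undefined.any():
            logger.warning("Wald statistic undefined in %d stage evaluations; treated as -inf", int(undefined.sum()))
            stat = np.where(undefined, -np.inf, stat)

    stopped_at = np.zeros(reps, dtype=np.int64)
    rejected = np.zeros(reps, dtype=bool)
    active = np.ones(reps, dtype=bool)
    for k in range(K):
        tk = stat[:, k]
        rej = active & (tk >= design.r[k])
        acc = active & (tk < design.a[k])
        stop = rej | acc
        stopped_at[stop] = k + 1
        rejected[rej] = True
        active &= ~stop
    # a_K = r_K guarantees no replicate remains active
    assert not active.any()
    return stopped_at, rejected, y1, y2


def simulate_trial(
    design: GroupSequentialDesign, rates: PoissonRates, rng: np.random.Generator
) -> TrialRealization:
    """Simulate a single trial under the design's stopping rules."""
    stopped_at, rejected, y1, y2 = _simulate_batch(design, rates, 1, rng)
    k_stop = int(stopped_at[0])
    return TrialRealization(
        stage_sums=tuple((int(y1[0, k]), int(y2[0, k])) for k in range(k_stop)),
        stopped_at=k_stop,
        decision="reject" if rejected[0] else "accept",
        total_sample_size=2 * design.n * k_stop,
    )


def empirical_error_rates(
    design: GroupSequentialDesign, rates: PoissonRates, replicates: int, seed: int
) -> EmpiricalOperatingCharacteristics:
    """Empirical stopping rates over ``replicates`` independent trials.

    Deterministic given the seed: all replicate draws come from a single
    seeded generator in one vectorized pass.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    stopped_at, rejected, _, _ = _simulate_batch(design, rates, replicates, rng)
    p_rej = float(np.mean(rejected))
    p_acc = 1.0 - p_rej
    se = math.sqrt(p_rej * p_acc / replicates)
    return EmpiricalOperatingCharacteristics(
        reject_rate=p_rej,
        accept_rate=p_acc,
        mean_sample_size=float(np.mean(2 * design.n * stopped_at)),
        replicates=replicates,
        standard_errors=(se, se),
        seed=seed,
    )
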