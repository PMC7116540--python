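"""Engine-dispatching evaluation of a design's operating characteristics."""

from __future__ import annotations

from typing import Tuple

import numpy as np

from . import exact, normal
from .types import DesignProblem, GroupSequentialDesign, OperatingCharacteristics, PoissonRates

__all__ = ["stage_probs", "ess", "max_error", "evaluate_design"]


def stage_probs(design: GroupSequentialDesign, rates: PoissonRates) -> Tuple[np.ndarray, np.ndarray]:
    """Per-stage (accept, reject) probabilities under the design's own engine."""
    if design.engine == "exact":
        return exact.exact_stage_probs(design, rates)
    return normal.normal_stage_probs(design, rates)


def ess(design: GroupSequentialDesign, rates: PoissonRates) -> float:
    """Expected total sample size under the design's own engine."""
    if design.engine == "exact":
        return exact.exact_ess(design, rates)
    return normal.normal_ess(design, rates)


def max_error(design: GroupSequentialDesign, problem: DesignProblem, which: str) -> Tuple[float, float]:
    """Maximal error rate and its location.

    For the normal engine the location is fixed by theory (null: any point,
    reported at the interval midpoint; alternative: the supremum).
    """
    if design.engine == "exact":
        return exact.exact_max_error(design, problem, which)
    value = normal.normal_max_error(design, problem, which)
    if which == "typeI":
        arg = 0.5 * (problem.lambda_null[0] + problem.lambda_null[1])
    else:
        arg = problem.lambda_alt[1]
    return value, arg


def evaluate_design(design: GroupSequentialDesign, problem: DesignProblem) -> OperatingCharacteristics:
    """Full operating characteristics: maximal error rates, stage-wise
    stopping probabilities at the null ESS rates, and ESS at the reporting
    rates ``(lambda_ess, lambda_ess)`` and ``(lambda_ess, lambda_ess - delta)``."""
    alpha_max, arg_null = max_error(design, problem, "typeI")
    beta_max, arg_alt = max_error(design, problem, "typeII")
    A, R = stage_probs(design, problem.ess_null_rates)
    return OperatingCharacteristics(
        alpha_max=alpha_max,
        beta_max=beta_max,
        argmax_lambda_null=arg_null,
        argmax_lambda_alt=arg_alt,
        stage_accept=tuple(float(x) for x in A),
        stage_reject=tuple(float(x) for x in R),
        ess_null=ess(design, problem.ess_null_rates),
        ess_alt=ess(design, problem.ess_alt_rates),
        max_n=design.max_sample_size,
    )
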