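"""Domain types for two-arm Poisson group sequential designs.

A trial accrues ``n`` subjects per arm per stage, for up to ``K`` stages.
Subject counts on arm ``j`` are Poisson with mean rate ``lambda_j``.  At each
analysis a test statistic is compared with futility (``a``) and efficacy
(``r``) boundaries: the trial stops to reject the null when the statistic is
at or above ``r_k``, stops to accept when below ``a_k``, and otherwise
continues.  Interim stages require ``a_k < r_k``; the final stage has
``a_K = r_K`` so a decision is always reached.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence, Tuple

Engine = Literal["exact", "normal"]

__all__ = [
    "Engine",
    "PoissonRates",
    "StageStatisticDistribution",
    "DesignProblem",
    "GroupSequentialDesign",
    "SpendingPlan",
    "OptimalityWeights",
    "SearchLimits",
    "OperatingCharacteristics",
    "TrialRealization",
    "EmpiricalOperatingCharacteristics",
    "Infeasible",
    "GroupSizeSearchFailure",
]


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


@dataclass(frozen=True)
class PoissonRates:
    """Mean event rates (events per observation period) on the two arms."""

    lambda1: float
    lambda2: float

    def __post_init__(self) -> None:
        for name in ("lambda1", "lambda2"):
            v = getattr(self, name)
            _require(math.isfinite(v) and v > 0, f"{name} must be a positive finite real, got {v!r}")

    @property
    def total(self) -> float:
        return self.lambda1 + self.lambda2

    @property
    def difference(self) -> float:
        return self.lambda1 - self.lambda2


@dataclass(frozen=True)
class StageStatisticDistribution:
    """Distribution of the stage-wise difference of arm totals.

    With ``n`` subjects per arm in the stage, each arm total is Poisson with
    mean ``n * lambda_j`` and their difference follows a Skellam distribution
    with mean ``n (lambda1 - lambda2)`` and variance ``n (lambda1 + lambda2)``.
    """

    n: int
    rates: PoissonRates

    def __post_init__(self) -> None:
        _require(isinstance(self.n, (int,)) and self.n >= 1, f"n must be a positive integer, got {self.n!r}")

    @property
    def mu1(self) -> float:
        return self.n * self.rates.lambda1

    @property
    def mu2(self) -> float:
        return self.n * self.rates.lambda2


def _as_interval(value: Sequence[float], name: str) -> Tuple[float, float]:
    lo, hi = (float(value[0]), float(value[1])) if not isinstance(value, (int, float)) else (float(value), float(value))
    _require(math.isfinite(lo) and math.isfinite(hi), f"{name} endpoints must be finite")
    _require(lo > 0, f"{name} lower endpoint must be positive, got {lo}")
    _require(lo <= hi, f"{name} must satisfy lower <= upper, got [{lo}, {hi}]")
    return (lo, hi)


@dataclass(frozen=True)
class DesignProblem:
    """A design problem: composite hypothesis sets, effect size and error targets.

    The null hypothesis is ``lambda1 = lambda2 in lambda_null`` and the trial
    is powered for ``lambda1 = lambda2 + delta`` with ``lambda1 in
    lambda_alt``.  ``lambda_ess`` is the arm-1 rate at which expected sample
    sizes are reported.
    """

    lambda_null: Tuple[float, float]
    lambda_alt: Tuple[float, float]
    delta: float
    alpha: float
    beta: float
    lambda_ess: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "lambda_null", _as_interval(self.lambda_null, "lambda_null"))
        object.__setattr__(self, "lambda_alt", _as_interval(self.lambda_alt, "lambda_alt"))
        _require(self.delta > 0, f"delta must be positive, got {self.delta}")
        _require(
            self.delta < self.lambda_alt[0],
            f"delta must be below inf(lambda_alt) so the arm-2 rate stays positive "
            f"(delta={self.delta}, inf(lambda_alt)={self.lambda_alt[0]})",
        )
        _require(0 < self.alpha < 1, f"alpha must lie in (0, 1), got {self.alpha}")
        _require(0 < self.beta < 1, f"beta must lie in (0, 1), got {self.beta}")
        _require(self.lambda_ess > 0, f"lambda_ess must be positive, got {self.lambda_ess}")

    def null_rates(self, lam: float) -> PoissonRates:
        return PoissonRates(lam, lam)

    def alt_rates(self, lam1: float) -> PoissonRates:
        return PoissonRates(lam1, lam1 - self.delta)

    @property
    def ess_null_rates(self) -> PoissonRates:
        return PoissonRates(self.lambda_ess, self.lambda_ess)

    @property
    def ess_alt_rates(self) -> PoissonRates:
        return PoissonRates(self.lambda_ess, self.lambda_ess - self.delta)


@dataclass(frozen=True)
class GroupSequentialDesign:
    """A K-stage design: group size and stopping boundaries, plus the engine
    (``exact`` integer boundaries on the cumulative count difference, or
    ``normal`` real boundaries on the Wald statistic)."""

    K: int
    n: int
    a: Tuple[float, ...]
    r: Tuple[float, ...]
    engine: Engine

    def __post_init__(self) -> None:
        _require(self.K >= 1, f"K must be >= 1, got {self.K}")
        _require(self.n >= 1, f"n must be >= 1, got {self.n}")
        a = tuple(float(x) for x in self.a)
        r = tuple(float(x) for x in self.r)
        _require(len(a) == self.K and len(r) == self.K, "boundary vectors must have length K")
        _require(self.engine in ("exact", "normal"), f"engine must be 'exact' or 'normal', got {self.engine!r}")
        if self.engine == "exact":
            for v in a + r:
                _require(float(v).is_integer(), f"exact-engine boundaries must be integers, got {v}")
            a = tuple(int(x) for x in a)
            r = tuple(int(x) for x in r)
        for k in range(self.K - 1):
            _require(a[k] < r[k], f"interim stage {k + 1} requires a_k < r_k, got a={a[k]}, r={r[k]}")
        _require(a[-1] == r[-1], f"final stage requires a_K = r_K, got a={a[-1]}, r={r[-1]}")
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "r", r)

    @property
    def max_sample_size(self) -> int:
        """Maximal total sample size over both arms, 2Kn."""
        return 2 * self.K * self.n


@dataclass(frozen=True)
class SpendingPlan:
    """Error spending vectors: ``pi_R`` allocates the type-I budget alpha
    across stages; ``pi_A`` allocates the type-II budget beta."""

    pi_A: Tuple[float, ...]
    pi_R: Tuple[float, ...]

    def __post_init__(self) -> None:
        pa = tuple(float(x) for x in self.pi_A)
        pr = tuple(float(x) for x in self.pi_R)
        _require(len(pa) == len(pr) and len(pa) >= 1, "pi_A and pi_R must be nonempty and of equal length")
        for v in pa + pr:
            _require(v >= 0, f"spending entries must be nonnegative, got {v}")
        object.__setattr__(self, "pi_A", pa)
        object.__setattr__(self, "pi_R", pr)

    @property
    def K(self) -> int:
        return len(self.pi_A)

    def validate_for(self, problem: DesignProblem, tol: float = 1e-9) -> None:
        _require(
            abs(sum(self.pi_R) - problem.alpha) <= tol,
            f"pi_R must sum to alpha={problem.alpha}, got {sum(self.pi_R)}",
        )
        _require(
            abs(sum(self.pi_A) - problem.beta) <= tol,
            f"pi_A must sum to beta={problem.beta}, got {sum(self.pi_A)}",
        )


@dataclass(frozen=True)
class OptimalityWeights:
    """Weights of the design criterion
    ``w1 * ESS(null) + w2 * ESS(alternative) + w3 * 2Kn`` (lower is better)."""

    w1: float
    w2: float
    w3: float

    def __post_init__(self) -> None:
        for name in ("w1", "w2", "w3"):
            _require(getattr(self, name) >= 0, f"{name} must be nonnegative")
        _require(self.w1 + self.w2 > 0, "w1 + w2 must be positive: the maximal sample size alone does not discriminate between designs")


@dataclass(frozen=True)
class SearchLimits:
    """Limits of the exhaustive two-stage search.

    ``epsilon`` bounds the stage-1 stopping probabilities used to delimit the
    boundary box; ``n_max_factor`` multiplies the fixed-sample group size to
    cap the group-size scan.
    """

    epsilon: float = 1e-7
    n_max_factor: float = 1.5

    def __post_init__(self) -> None:
        _require(0 < self.epsilon < 0.01, f"epsilon must lie in (0, 0.01), got {self.epsilon}")
        _require(self.n_max_factor > 0, "n_max_factor must be positive")


@dataclass
class OperatingCharacteristics:
    """Evaluated operating characteristics of a design."""

    alpha_max: float
    beta_max: float
    argmax_lambda_null: float
    argmax_lambda_alt: float
    stage_accept: Tuple[float, ...]
    stage_reject: Tuple[float, ...]
    ess_null: float
    ess_alt: float
    max_n: int


@dataclass(frozen=True)
class TrialRealization:
    """One simulated trial: per-stage arm totals up to the stopping stage,
    the stage at which the trial stopped, and the decision reached."""

    stage_sums: Tuple[Tuple[int, int], ...]
    stopped_at: int
    decision: Literal["reject", "accept"]
    total_sample_size: int


@dataclass(frozen=True)
class EmpiricalOperatingCharacteristics:
    """Monte Carlo estimates of a design's stopping behaviour."""

    reject_rate: float
    accept_rate: float
    mean_sample_size: float
    replicates: int
    standard_errors: Tuple[float, float]
    seed: int


@dataclass(frozen=True)
class Infeasible:
    """Returned when a spending plan admits no valid boundaries at a group size."""

    reason: str
    stage: Optional[int] = None
    n: Optional[int] = None


@dataclass(frozen=True)
class GroupSizeSearchFailure:
    """Returned when no group size up to the cap meets the power requirement."""

    best_n: Optional[int]
    best_beta: Optional[float]
    reason: str
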