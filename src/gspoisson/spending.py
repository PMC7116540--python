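"""Boundary determination by error spending, group-size search, and design search.

Spending vectors ``pi_R`` (summing to alpha) and ``pi_A`` (summing to beta)
fix the boundaries recursively: at each interim stage the efficacy boundary
``r_k`` is the smallest value whose stage-k rejection probability stays
within ``pi_Rk`` (maximized over the null rate set for the exact engine), and
the futility boundary ``a_k`` is then the largest value whose stage-k
acceptance probability stays within ``pi_Ak`` (maximized over the
alternative set).  The final stage sets ``a_K = r_K`` from the rejection
rule, which guarantees type-I control at level alpha by construction.  The
group size is the smallest ``n`` for which the implied boundaries meet the
power requirement.

Near-optimal designs come from ranking a grid of spending plans under the
weighted criterion ``w1 ESS(null) + w2 ESS(alt) + w3 2Kn``.  For two-stage
exact designs an epsilon-bounded exhaustive search over integer boundaries
is also provided.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
from joblib import Parallel, delayed
from scipy import optimize, stats

from . import exact as exact_mod
from . import normal as normal_mod
from . import skellam
from ._optim import interval_max, largest_int_where, max_at_most, smallest_int_where
from .evaluate import ess as _ess
from .types import (
    DesignProblem,
    GroupSequentialDesign,
    GroupSizeSearchFailure,
    Infeasible,
    OptimalityWeights,
    PoissonRates,
    SearchLimits,
    SpendingPlan,
)

logger = logging.getLogger(__name__)

__all__ = [
    "derive_boundaries",
    "find_group_size",
    "optimality_score",
    "grid_search",
    "exhaustive_search_k2",
    "two_stage_spending_grid",
    "three_stage_spending_grid",
    "RankedDesign",
]

_TOL = 1e-12


# ---------------------------------------------------------------------------
# boundary derivation
# ---------------------------------------------------------------------------


def derive_boundaries(
    n: int, plan: SpendingPlan, problem: DesignProblem, engine: str
) -> Union[GroupSequentialDesign, Infeasible]:
    """Boundaries implied by a spending plan at group size ``n``.

    Returns an :class:`Infeasible` value (not an exception) when the implied
    interim boundaries cross or a stage's spending target cannot be met.
    """
    plan.validate_for(problem)
    if n < 1:
        raise ValueError("n must be >= 1")
    if engine == "exact":
        return _derive_exact(n, plan, problem)
    if engine == "normal":
        return _derive_normal(n, plan, problem)
    raise ValueError(f"engine must be 'exact' or 'normal', got {engine!r}")


def _continuation_max(
    k: int, n: int, a_prev: Tuple[int, ...], r_prev: Tuple[int, ...], lo: float, hi: float, null: bool, problem: DesignProblem
) -> float:
    """Max over the rate interval of the probability of reaching stage k."""
    if k == 1:
        return 1.0

    def cont(lam: float) -> float:
        rates = problem.null_rates(lam) if null else problem.alt_rates(lam)
        tables = exact_mod._h_tables(n, a_prev, r_prev, rates.lambda1, rates.lambda2)
        return float(tables[k - 2][1].sum())

    value, _ = interval_max(cont, lo, hi)
    return value


def _derive_exact(n: int, plan: SpendingPlan, problem: DesignProblem) -> Union[GroupSequentialDesign, Infeasible]:
    K = plan.K
    l0lo, l0hi = problem.lambda_null
    l1lo, l1hi = problem.lambda_alt
    a: List[int] = []
    r: List[int] = []
    for k in range(1, K + 1):
        pi_r = plan.pi_R[k - 1]
        a_prev, r_prev = tuple(a), tuple(r)
        if pi_r <= 0:
            return Infeasible("zero rejection spending is not attainable with finite integer boundaries", stage=k, n=n)
        if _continuation_max(k, n, a_prev, r_prev, l0lo, l0hi, True, problem) <= pi_r:
            return Infeasible("rejection spending exceeds the probability of reaching the stage", stage=k, n=n)

        def pred_r(rk: int) -> bool:
            return max_at_most(
                lambda lam: exact_mod.stage_reject_prob(k, n, a_prev, r_prev, rk, problem.null_rates(lam)),
                l0lo,
                l0hi,
                pi_r,
            )

        sigma = math.sqrt(2.0 * k * n * l0hi)
        start = int(round(stats.norm.ppf(max(1.0 - pi_r, 0.5)) * sigma))
        rk = smallest_int_where(pred_r, start, step=max(1, int(sigma / 2)))
        if k == K:
            a.append(rk)
            r.append(rk)
            break
        pi_a = plan.pi_A[k - 1]
        if pi_a <= 0:
            return Infeasible("zero acceptance spending is not attainable with finite integer boundaries", stage=k, n=n)

        def pred_a(ak: int) -> bool:
            return max_at_most(
                lambda lam: exact_mod.stage_accept_prob(k, n, a_prev, r_prev, ak, problem.alt_rates(lam)),
                l1lo,
                l1hi,
                pi_a,
            )

        # the spending-implied futility boundary must leave a continuation region
        if pred_a(rk):
            return Infeasible("interim boundaries cross (a_k >= r_k)", stage=k, n=n)
        sig_alt = math.sqrt(k * n * (2.0 * l1hi - problem.delta))
        start_a = int(round(k * n * problem.delta + stats.norm.ppf(min(pi_a, 0.5)) * sig_alt))
        ak = largest_int_where(pred_a, min(start_a, rk - 1), step=max(1, int(sig_alt / 2)))
        a.append(ak)
        r.append(rk)
    return GroupSequentialDesign(K=K, n=n, a=tuple(a), r=tuple(r), engine="exact")


def _derive_normal(n: int, plan: SpendingPlan, problem: DesignProblem) -> Union[GroupSequentialDesign, Infeasible]:
    K = plan.K
    lam_null = 0.5 * (problem.lambda_null[0] + problem.lambda_null[1])
    null_rates = problem.null_rates(lam_null)
    alt_rates = problem.alt_rates(problem.lambda_alt[1])
    a: List[float] = []
    r: List[float] = []
    lim = 40.0
    for k in range(1, K + 1):
        pi_r = plan.pi_R[k - 1]
        a_prev, r_prev = tuple(a), tuple(r)
        if pi_r <= 0:
            return Infeasible("zero rejection spending implies an unbounded boundary", stage=k, n=n)

        def f_r(rk: float) -> float:
            return normal_mod.stage_reject_prob(k, n, a_prev, r_prev, rk, null_rates) - pi_r

        if f_r(-lim) <= 0:
            return Infeasible("rejection spending exceeds the probability of reaching the stage", stage=k, n=n)
        rk = float(optimize.brentq(f_r, -lim, lim, xtol=1e-12))
        if k == K:
            a.append(rk)
            r.append(rk)
            break
        pi_a = plan.pi_A[k - 1]
        if pi_a <= 0:
            return Infeasible("zero acceptance spending implies an unbounded boundary", stage=k, n=n)

        def f_a(ak: float) -> float:
            return normal_mod.stage_accept_prob(k, n, a_prev, r_prev, ak, alt_rates) - pi_a

        if f_a(rk) <= 0:
            # the spending-implied a_k would sit at or above r_k
            return Infeasible("interim boundaries cross (a_k >= r_k)", stage=k, n=n)
        ak = float(optimize.brentq(f_a, -lim, rk, xtol=1e-12))
        if ak >= rk:
            return Infeasible("interim boundaries cross (a_k >= r_k)", stage=k, n=n)
        a.append(ak)
        r.append(rk)
    return GroupSequentialDesign(K=K, n=n, a=tuple(a), r=tuple(r), engine="normal")


# ---------------------------------------------------------------------------
# group size search
# ---------------------------------------------------------------------------


def find_group_size(
    plan: SpendingPlan, problem: DesignProblem, engine: str, n_cap: int
) -> Union[GroupSequentialDesign, GroupSizeSearchFailure]:
    """Smallest group size whose spending-derived boundaries meet the power target.

    Scans ``n = 1, 2, ..., n_cap`` (the maximal type-II error is not known to
    be monotone in ``n`` for the exact engine, so no bisection is attempted).
    """
    if n_cap < 1:
        raise ValueError("n_cap must be >= 1")
    plan.validate_for(problem)
    best_n: Optional[int] = None
    best_beta: Optional[float] = None
    for n in range(1, n_cap + 1):
        design = derive_boundaries(n, plan, problem, engine)
        if isinstance(design, Infeasible):
            logger.debug("n=%d infeasible: %s", n, design.reason)
            continue
        if engine == "exact":
            beta_val, _ = exact_mod.exact_max_error(design, problem, "typeII")
        else:
            beta_val = normal_mod.normal_max_error(design, problem, "typeII")
        logger.debug("plan=%s n=%d a=%s r=%s beta'=%.6f", plan, n, design.a, design.r, beta_val)
        if beta_val <= problem.beta + _TOL:
            return design
        if best_beta is None or beta_val < best_beta:
            best_n, best_beta = n, beta_val
    return GroupSizeSearchFailure(
        best_n=best_n,
        best_beta=best_beta,
        reason=f"no n <= {n_cap} attains maximal type-II error <= {problem.beta}"
        + (f"; best achieved {best_beta:.4f} at n={best_n}" if best_beta is not None else ""),
    )


def _fixed_sample_group_size(problem: DesignProblem, engine: str, n_cap: int = 2000) -> int:
    """Group size of the single-stage design spending everything at once."""
    plan = SpendingPlan(pi_A=(problem.beta,), pi_R=(problem.alpha,))
    result = find_group_size(plan, problem, engine, n_cap=n_cap)
    if isinstance(result, GroupSizeSearchFailure):
        raise RuntimeError(f"no single-stage design found up to n={n_cap}: {result.reason}")
    return result.n


# ---------------------------------------------------------------------------
# optimality criterion and grid search
# ---------------------------------------------------------------------------


def optimality_score(
    design: GroupSequentialDesign, weights: OptimalityWeights, problem: DesignProblem
) -> float:
    """Weighted criterion ``w1 ESS(null) + w2 ESS(alt) + w3 2Kn`` (lower is better)."""
    score = weights.w3 * design.max_sample_size
    if weights.w1 > 0:
        score += weights.w1 * _ess(design, problem.ess_null_rates)
    if weights.w2 > 0:
        score += weights.w2 * _ess(design, problem.ess_alt_rates)
    return score


@dataclass(frozen=True)
class RankedDesign:
    plan: SpendingPlan
    design: GroupSequentialDesign
    score: float


def _fit_plan(plan, problem, engine, n_cap, weights):
    result = find_group_size(plan, problem, engine, n_cap)
    if isinstance(result, GroupSizeSearchFailure):
        logger.info("plan piA=%s piR=%s: %s", plan.pi_A, plan.pi_R, result.reason)
        return None
    score = optimality_score(result, weights, problem)
    logger.info(
        "plan piA=%s piR=%s -> n=%d a=%s r=%s score=%.4f",
        plan.pi_A, plan.pi_R, result.n, result.a, result.r, score,
    )
    return RankedDesign(plan=plan, design=result, score=score)


def grid_search(
    grid: Sequence[SpendingPlan],
    weights: OptimalityWeights,
    problem: DesignProblem,
    engine: str,
    K: int,
    n_cap: Optional[int] = None,
    n_jobs: int = 1,
) -> List[RankedDesign]:
    """Rank the designs implied by a grid of spending plans.

    Each plan is fitted independently (parallelizable; the ranking does not
    depend on the worker count).  Ties are broken by smaller maximal sample
    size, then smaller group size, then lexicographically smaller ``pi_R``.
    """
    if not grid:
        raise ValueError("spending grid must be nonempty")
    plans: List[SpendingPlan] = []
    for plan in grid:
        if plan.K != K:
            logger.warning("dropping plan %s: K=%d does not match requested K=%d", plan, plan.K, K)
            continue
        try:
            plan.validate_for(problem)
        except ValueError as exc:
            logger.warning("dropping nonconforming plan %s: %s", plan, exc)
            continue
        plans.append(plan)
    if n_cap is None:
        n_cap = 2 * _fixed_sample_group_size(problem, engine)
    results = Parallel(n_jobs=n_jobs)(
        delayed(_fit_plan)(plan, problem, engine, n_cap, weights) for plan in plans
    )
    ranked = [x for x in results if x is not None]
    if not ranked:
        logger.warning("no feasible design among %d plans (n_cap=%d)", len(plans), n_cap)
    ranked.sort(key=lambda x: (x.score, x.design.max_sample_size, x.design.n, x.plan.pi_R))
    return ranked


# ---------------------------------------------------------------------------
# exhaustive two-stage search
# ---------------------------------------------------------------------------


def _stage1_limits(n: int, problem: DesignProblem, eps: float) -> Tuple[int, int]:
    """epsilon-bounded stage-1 boundary limits.

    ``a_star`` is the largest integer whose stage-1 acceptance probability is
    at most eps everywhere on the null set; ``r_star`` the smallest integer
    whose stage-1 rejection probability is at most eps everywhere on the
    alternative set.
    """
    l0lo, l0hi = problem.lambda_null
    l1lo, l1hi = problem.lambda_alt
    delta = problem.delta

    def pred_a(aa: int) -> bool:
        return max_at_most(lambda lam: float(skellam.cdf(aa - 1, n * lam, n * lam)), l0lo, l0hi, eps)

    def pred_r(rr: int) -> bool:
        return max_at_most(
            lambda lam: float(skellam.sf(rr - 1, n * lam, n * (lam - delta))), l1lo, l1hi, eps
        )

    sig0 = math.sqrt(2.0 * n * l0hi)
    sig1 = math.sqrt(n * (2.0 * l1hi - delta))
    a_star = largest_int_where(pred_a, int(-6.0 * sig0), step=max(1, int(sig0)))
    r_star = smallest_int_where(pred_r, int(n * delta + 6.0 * sig1), step=max(1, int(sig1)))
    return a_star, r_star


def _k2_type_one(n: int, a1: int, r1: int, c: int, lam: float) -> float:
    """Total rejection probability of the design (a1, c), (r1, c) at lambda1=lambda2=lam."""
    rates = PoissonRates(lam, lam)
    p = exact_mod.stage_reject_prob(1, n, (), (), r1, rates)
    p += exact_mod.stage_reject_prob(2, n, (a1,), (r1,), c, rates)
    return p


def _complete_k2(
    problem: DesignProblem, n: int, a1: int, r1: int, a_star: int, r_star: int
) -> Optional[GroupSequentialDesign]:
    """Smallest final boundary controlling alpha, then the power check."""
    l0lo, l0hi = problem.lambda_null
    lo, hi = a1 + a_star, r1 + r_star
    alpha = problem.alpha

    def pred(c: int) -> bool:
        return max_at_most(lambda lam: _k2_type_one(n, a1, r1, c, lam), l0lo, l0hi, alpha + _TOL)

    if not pred(hi):
        return None
    if pred(lo):
        c = lo
    else:
        clo, chi = lo, hi
        while chi - clo > 1:
            mid = (clo + chi) // 2
            if pred(mid):
                chi = mid
            else:
                clo = mid
        c = chi
    design = GroupSequentialDesign(K=2, n=n, a=(a1, c), r=(r1, c), engine="exact")
    beta_val, _ = exact_mod.exact_max_error(design, problem, "typeII")
    if beta_val <= problem.beta + _TOL:
        return design
    return None


def _enumerate_pairs(a_star: int, r_star: int) -> Tuple[np.ndarray, np.ndarray]:
    """All (a1, r1) with a1 in [a_star, r_star - 2] and r1 in [a1 + 2, r_star]."""
    a1s = np.arange(a_star, r_star - 1)
    counts = r_star - a1s - 1
    a1v = np.repeat(a1s, counts)
    cum0 = np.concatenate(([0], np.cumsum(counts)[:-1]))
    j = np.arange(int(counts.sum())) - np.repeat(cum0, counts)
    r1v = a1v + 2 + j
    return a1v.astype(np.int64), r1v.astype(np.int64)


def _prune_pairs(
    n: int,
    a_star: int,
    r_star: int,
    problem: DesignProblem,
    null_lams: np.ndarray,
    alt_lams: np.ndarray,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Conservative feasibility screen of all (a1, r1) pairs at group size n.

    Works on a finite grid of rates, so the screened maxima never exceed the
    true maxima: every truly feasible pair survives.  Survivors are later
    re-checked with the full Brent-refined maximization.
    """
    alpha, beta, delta = problem.alpha, problem.beta, problem.delta
    tv = np.arange(a_star, r_star)
    T = len(tv)
    ncol = T + 1
    a1v, r1v = _enumerate_pairs(a_star, r_star)
    col_a1 = a1v - a_star
    col_r1 = r1v - a_star
    r2lo = 2 * a_star
    r2hi = 2 * r_star
    qlo = r2lo - 1 - (r_star - 1)
    qhi = r2hi - 1 - a_star
    qgrid = np.arange(qlo, qhi + 1)
    r2vals = np.arange(r2lo, r2hi + 1)
    idx = (r2vals[:, None] - 1 - tv[None, :]) - qlo

    feas = np.ones(a1v.shape, dtype=bool)
    a2min = (a1v + a_star).copy()
    a2hi = r1v + r_star

    for lam in null_lams:
        mu = n * lam
        g = skellam.pmf(tv, mu, mu)
        qtab = skellam.sf(qgrid, mu, mu)
        flat = np.concatenate(
            [np.zeros((len(r2vals), 1)), np.cumsum(g * qtab[idx], axis=1)], axis=1
        ).ravel()
        act = np.nonzero(feas)[0]
        if act.size == 0:
            return a1v[:0], r1v[:0], a2min[:0]
        r1_act, a1c, r1c = r1v[act], col_a1[act], col_r1[act]
        R1 = qtab[(r1_act - 1) - qlo]

        def total(x: np.ndarray) -> np.ndarray:
            base = (x - r2lo) * ncol
            return R1 + flat[base + r1c] - flat[base + a1c]

        hi = a2hi[act]
        ok_hi = total(hi) <= alpha + _TOL
        feas[act[~ok_hi]] = False
        sub = act[ok_hi]
        if sub.size == 0:
            continue
        lo_b = a2min[sub].copy()
        hi_b = a2hi[sub].copy()
        R1, r1c, a1c = R1[ok_hi], r1c[ok_hi], a1c[ok_hi]
        while True:
            open_ = lo_b < hi_b
            if not open_.any():
                break
            mid = (lo_b + hi_b) // 2
            ok = total(mid) <= alpha + _TOL
            hi_b = np.where(open_ & ok, mid, hi_b)
            lo_b = np.where(open_ & ~ok, mid + 1, lo_b)
        a2min[sub] = np.maximum(a2min[sub], lo_b)

    for lam in alt_lams:
        mu1, mu2 = n * lam, n * (lam - delta)
        g = skellam.pmf(tv, mu1, mu2)
        gtab = skellam.cdf(qgrid, mu1, mu2)
        flat = np.concatenate(
            [np.zeros((len(r2vals), 1)), np.cumsum(g * gtab[idx], axis=1)], axis=1
        ).ravel()
        act = np.nonzero(feas)[0]
        if act.size == 0:
            return a1v[:0], r1v[:0], a2min[:0]
        A1 = gtab[(a1v[act] - 1) - qlo]
        base = (a2min[act] - r2lo) * ncol
        A2 = flat[base + col_r1[act]] - flat[base + col_a1[act]]
        feas[act] &= (A1 + A2) <= beta + _TOL

    keep = np.nonzero(feas)[0]
    return a1v[keep], r1v[keep], a2min[keep]


def exhaustive_search_k2(
    problem: DesignProblem,
    weights: OptimalityWeights,
    limits: Optional[SearchLimits] = None,
    n_fixed: Optional[int] = None,
    prune_grid_points: int = 5,
) -> Union[GroupSequentialDesign, GroupSizeSearchFailure]:
    """Optimal two-stage exact design by epsilon-bounded exhaustive search.

    For each group size ``n`` up to ``n_max_factor * n_fixed`` the stage-1
    boundary box ``a1 in [a*, r* - 2]``, ``r1 in [a1 + 2, r*]`` is
    enumerated, with ``a2 = r2`` taken as the smallest integer in
    ``[a1 + a*, r1 + r*]`` controlling the maximal type-I error.  For two
    stages the criterion depends only on ``(n, a1, r1)`` (a trial that
    continues always stops at stage 2), so candidates are ranked by score
    first and checked for exact feasibility in that order; the first feasible
    candidate is the optimum.
    """
    limits = limits or SearchLimits()
    if n_fixed is None:
        n_fixed = _fixed_sample_group_size(problem, "exact")
    n_max = int(math.floor(limits.n_max_factor * n_fixed))
    l0lo, l0hi = problem.lambda_null
    l1lo, l1hi = problem.lambda_alt
    g = max(1, prune_grid_points)
    null_lams = np.linspace(l0lo, l0hi, 1 if l0lo == l0hi else g)
    alt_lams = np.linspace(l1lo, l1hi, 1 if l1lo == l1hi else g)
    lam_e = problem.lambda_ess

    scores: List[np.ndarray] = []
    ns: List[np.ndarray] = []
    a1s: List[np.ndarray] = []
    r1s: List[np.ndarray] = []
    star: dict[int, Tuple[int, int]] = {}

    for n in range(1, n_max + 1):
        a_star, r_star = _stage1_limits(n, problem, limits.epsilon)
        if r_star - a_star < 2:
            continue
        star[n] = (a_star, r_star)
        a1v, r1v, _ = _prune_pairs(n, a_star, r_star, problem, null_lams, alt_lams)
        if a1v.size == 0:
            continue
        # the score depends only on the stage-1 stopping probability
        off = a_star - 1
        bgrid = np.arange(a_star - 1, r_star)
        score = np.full(a1v.shape, weights.w3 * 4.0 * n)
        if weights.w1 > 0:
            mu = n * lam_e
            cdf0 = skellam.cdf(bgrid, mu, mu)
            sf0 = skellam.sf(bgrid, mu, mu)
            p1 = cdf0[a1v - 1 - off] + sf0[r1v - 1 - off]
            score += weights.w1 * 2.0 * n * (2.0 - p1)
        if weights.w2 > 0:
            mu1, mu2 = n * lam_e, n * (lam_e - problem.delta)
            cdf1 = skellam.cdf(bgrid, mu1, mu2)
            sf1 = skellam.sf(bgrid, mu1, mu2)
            p1 = cdf1[a1v - 1 - off] + sf1[r1v - 1 - off]
            score += weights.w2 * 2.0 * n * (2.0 - p1)
        scores.append(score)
        ns.append(np.full(a1v.shape, n, dtype=np.int64))
        a1s.append(a1v)
        r1s.append(r1v)
        logger.info("exhaustive n=%d: a*=%d r*=%d, %d screened candidates", n, a_star, r_star, a1v.size)

    if not scores:
        return GroupSizeSearchFailure(None, None, "no candidate passed the feasibility screen")

    score_all = np.concatenate(scores)
    n_all = np.concatenate(ns)
    a1_all = np.concatenate(a1s)
    r1_all = np.concatenate(r1s)
    order = np.lexsort((r1_all, a1_all, n_all, score_all))

    checked = 0
    for i in order:
        n, a1, r1 = int(n_all[i]), int(a1_all[i]), int(r1_all[i])
        a_star, r_star = star[n]
        checked += 1
        design = _complete_k2(problem, n, a1, r1, a_star, r_star)
        if design is not None:
            logger.info(
                "exhaustive optimum after %d exact checks: n=%d a=%s r=%s score=%.4f",
                checked, n, design.a, design.r, float(score_all[i]),
            )
            return design
    return GroupSizeSearchFailure(None, None, "no screened candidate survived the exact feasibility check")


# ---------------------------------------------------------------------------
# study spending grids
# ---------------------------------------------------------------------------


def two_stage_spending_grid(
    problem: DesignProblem,
    pi_A1_values: Optional[Sequence[float]] = None,
    pi_R1_values: Optional[Sequence[float]] = None,
) -> List[SpendingPlan]:
    """Two-stage spending grid: stage-1 allocations, remainder at stage 2.

    Defaults cover pi_A1 in {0.02, 0.04, ..., 0.18} and pi_R1 in
    {0.005, 0.01, ..., 0.045}; plans whose stage-2 remainder would be
    negative are dropped with a warning.
    """
    if pi_A1_values is None:
        pi_A1_values = [round(0.02 * i, 10) for i in range(1, 10)]
    if pi_R1_values is None:
        pi_R1_values = [round(0.005 * i, 10) for i in range(1, 10)]
    plans = []
    for pa1 in pi_A1_values:
        for pr1 in pi_R1_values:
            pa2 = problem.beta - pa1
            pr2 = problem.alpha - pr1
            if pa2 < 0 or pr2 < 0:
                logger.warning("dropping plan piA1=%s piR1=%s: stage-2 remainder negative", pa1, pr1)
                continue
            plans.append(SpendingPlan(pi_A=(pa1, pa2), pi_R=(pr1, pr2)))
    return plans


def three_stage_spending_grid(
    problem: DesignProblem,
    pi_A_values: Optional[Sequence[float]] = None,
    pi_R_values: Optional[Sequence[float]] = None,
) -> List[SpendingPlan]:
    """Three-stage spending grid over stage-1/2 allocations, remainder at stage 3.

    Defaults cover (pi_A1, pi_A2) in {0.03, 0.06, 0.09, 0.12}^2 and
    (pi_R1, pi_R2) in {0.01, 0.015, ..., 0.035}^2.
    """
    if pi_A_values is None:
        pi_A_values = [0.03, 0.06, 0.09, 0.12]
    if pi_R_values is None:
        pi_R_values = [round(0.01 + 0.005 * i, 10) for i in range(6)]
    plans = []
    for pa1 in pi_A_values:
        for pa2 in pi_A_values:
            pa3 = problem.beta - pa1 - pa2
            if pa3 < 0:
                continue
            for pr1 in pi_R_values:
                for pr2 in pi_R_values:
                    pr3 = problem.alpha - pr1 - pr2
                    if pr3 < 0:
                        continue
                    plans.append(SpendingPlan(pi_A=(pa1, pa2, pa3), pi_R=(pr1, pr2, pr3)))
    return plans
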