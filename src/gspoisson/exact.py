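"""Exact operating characteristics of a K-stage design.

The test statistic at analysis k is the cumulative difference of arm totals
``T_Sk = (Y_11 - Y_21) + ... + (Y_1k - Y_2k)``; each stage increment is
Skellam distributed.  ``T_Sk`` itself has no simple distribution, but its
sub-density restricted to the event "the trial reached stage k" can be
computed over the continuation region by the recursion

    h_1(t) = g(t)
    h_k(t) = sum_{s = a_{k-1}}^{r_{k-1} - 1} h_{k-1}(s) g(t - s),   t in [a_k, r_k)

where ``g`` is the stage Skellam pmf.  Stage-wise acceptance and rejection
probabilities, maximal error rates over composite rate intervals, and the
expected sample size all follow from these sub-densities and the Skellam cdf.
"""

from __future__ import annotations

from functools import lru_cache
from typing import List, Tuple

import numpy as np

from . import skellam
from ._optim import interval_max
from .types import DesignProblem, GroupSequentialDesign, PoissonRates

__all__ = [
    "interim_subdensity",
    "exact_stage_probs",
    "exact_max_error",
    "exact_ess",
    "stage_reject_prob",
    "stage_accept_prob",
]


def _check_exact(design: GroupSequentialDesign) -> None:
    if design.engine != "exact":
        raise ValueError("this operation supports only engine='exact' designs")


@lru_cache(maxsize=4096)
def _h_tables(
    n: int, a: Tuple[int, ...], r: Tuple[int, ...], lam1: float, lam2: float
) -> Tuple[Tuple[int, np.ndarray], ...]:
    """Sub-density vectors h_1..h_m over their continuation regions.

    ``a``/``r`` are the boundaries of the first ``m`` (interim) stages; each
    entry of the result is ``(t0, values)`` with ``values[i] = h_k(t0 + i)``
    for ``t0 = a_k`` up to ``r_k - 1``.
    """
    mu1, mu2 = n * lam1, n * lam2
    tables: List[Tuple[int, np.ndarray]] = []
    h_prev: np.ndarray | None = None
    for k, (ak, rk) in enumerate(zip(a, r), start=1):
        ak, rk = int(np.floor(ak)), int(np.floor(rk))
        ts = np.arange(ak, rk)
        if k == 1:
            h = skellam.pmf(ts, mu1, mu2)
        else:
            a_prev, r_prev = int(np.floor(a[k - 2])), int(np.floor(r[k - 2]))
            dmin = ak - (r_prev - 1)
            dmax = (rk - 1) - a_prev
            g = skellam.pmf(np.arange(dmin, dmax + 1), mu1, mu2)
            full = np.convolve(h_prev, g)
            # full[i] is the mass at t = a_prev + dmin + i
            off = ak - (a_prev + dmin)
            h = full[off : off + (rk - ak)]
        tables.append((ak, h))
        h_prev = h
    return tuple(tables)


def interim_subdensity(
    k: int, t, design: GroupSequentialDesign, rates: PoissonRates
):
    """P(T_Sk = t and the trial reached stage k), for interim stages.

    For ``k = 1`` this is the stage Skellam pmf at any integer ``t``; for
    ``k >= 2`` it is defined over the continuation region ``[a_k, r_k)`` and
    evaluates to 0 outside it.
    """
    _check_exact(design)
    if not (1 <= k <= design.K - 1):
        raise ValueError(f"interim sub-densities exist only for 1 <= k <= K-1, got k={k} with K={design.K}")
    t_arr = np.asarray(t, dtype=np.int64)
    if k == 1:
        return skellam.pmf(t_arr, design.n * rates.lambda1, design.n * rates.lambda2)
    a = tuple(int(x) for x in design.a[:k])
    r = tuple(int(x) for x in design.r[:k])
    t0, h = _h_tables(design.n, a, r, rates.lambda1, rates.lambda2)[k - 1]
    idx = t_arr - t0
    valid = (idx >= 0) & (idx < len(h))
    out = np.where(valid, h[np.clip(idx, 0, len(h) - 1)], 0.0)
    return out if out.shape else float(out)


def stage_reject_prob(
    k: int,
    n: int,
    a_prev: Tuple[int, ...],
    r_prev: Tuple[int, ...],
    r_k: int,
    rates: PoissonRates,
) -> float:
    """P(continue through stages 1..k-1 and T_Sk >= r_k)."""
    mu1, mu2 = n * rates.lambda1, n * rates.lambda2
    if k == 1:
        return float(skellam.sf(r_k - 1, mu1, mu2))
    t0, h = _h_tables(n, tuple(a_prev), tuple(r_prev), rates.lambda1, rates.lambda2)[k - 2]
    s = np.arange(t0, t0 + len(h))
    return float(h @ skellam.sf(r_k - s - 1, mu1, mu2))


def stage_accept_prob(
    k: int,
    n: int,
    a_prev: Tuple[int, ...],
    r_prev: Tuple[int, ...],
    a_k: int,
    rates: PoissonRates,
) -> float:
    """P(continue through stages 1..k-1 and T_Sk < a_k)."""
    mu1, mu2 = n * rates.lambda1, n * rates.lambda2
    if k == 1:
        return float(skellam.cdf(a_k - 1, mu1, mu2))
    t0, h = _h_tables(n, tuple(a_prev), tuple(r_prev), rates.lambda1, rates.lambda2)[k - 2]
    s = np.arange(t0, t0 + len(h))
    return float(h @ skellam.cdf(a_k - s - 1, mu1, mu2))


def exact_stage_probs(
    design: GroupSequentialDesign, rates: PoissonRates
) -> Tuple[np.ndarray, np.ndarray]:
    """Per-stage probabilities of stopping to accept (A_k) and reject (R_k).

    Because ``a_K = r_K`` the stage probabilities sum to one: the trial
    always reaches a decision.
    """
    _check_exact(design)
    K, n = design.K, design.n
    a = tuple(int(x) for x in design.a)
    r = tuple(int(x) for x in design.r)
    A = np.empty(K)
    R = np.empty(K)
    for k in range(1, K + 1):
        prefix_a, prefix_r = a[: k - 1], r[: k - 1]
        A[k - 1] = stage_accept_prob(k, n, prefix_a, prefix_r, a[k - 1], rates)
        R[k - 1] = stage_reject_prob(k, n, prefix_a, prefix_r, r[k - 1], rates)
    return A, R


def exact_max_error(
    design: GroupSequentialDesign, problem: DesignProblem, which: str
) -> Tuple[float, float]:
    """Maximal type-I or type-II error rate over the composite rate set.

    Returns ``(value, argmax_lambda)``.  ``which='typeI'`` maximizes the
    total rejection probability under ``lambda1 = lambda2 = lambda`` over the
    null set; ``which='typeII'`` maximizes the total acceptance probability
    under ``lambda1 = lambda, lambda2 = lambda - delta`` over the
    alternative set.
    """
    _check_exact(design)
    if which == "typeI":
        lo, hi = problem.lambda_null

        def f(lam: float) -> float:
            _, R = exact_stage_probs(design, problem.null_rates(lam))
            return float(R.sum())

    elif which == "typeII":
        lo, hi = problem.lambda_alt

        def f(lam: float) -> float:
            A, _ = exact_stage_probs(design, problem.alt_rates(lam))
            return float(A.sum())

    else:
        raise ValueError(f"which must be 'typeI' or 'typeII', got {which!r}")
    return interval_max(f, lo, hi)


def exact_ess(design: GroupSequentialDesign, rates: PoissonRates) -> float:
    """Expected total sample size over both arms: 2n * sum_k k (A_k + R_k)."""
    A, R = exact_stage_probs(design, rates)
    k = np.arange(1, design.K + 1)
    return float(2 * design.n * np.sum(k * (A + R)))
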