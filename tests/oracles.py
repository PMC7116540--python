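"""Independent oracles used by the test suite.

Everything here deliberately avoids the package's own evaluation paths:
probability masses come from explicit Poisson convolutions or
``scipy.stats.skellam``, multi-stage stopping probabilities from exhaustive
enumeration of the truncated joint support, and the two-stage optimal search
from plain nested loops.
"""

from __future__ import annotations

import math
from typing import Dict, Optional, Tuple

import numpy as np
from scipy import stats


def poisson_convolution_pmf(t: int, mu1: float, mu2: float, jmax: int = 200) -> float:
    """P(Y1 - Y2 = t) by direct convolution of two Poisson pmfs."""
    j = np.arange(0, jmax + 1)
    return float(np.sum(stats.poisson.pmf(t + j, mu1) * stats.poisson.pmf(j, mu2)))


def poisson_convolution_cdf(t: int, mu1: float, mu2: float, lo: int = -400, jmax: int = 200) -> float:
    """P(Y1 - Y2 <= t) by summing the convolution pmf from a far lower tail."""
    return float(sum(poisson_convolution_pmf(s, mu1, mu2, jmax) for s in range(lo, t + 1)))


def enumerate_k2_stage_probs(
    n: int,
    a: Tuple[int, int],
    r: Tuple[int, int],
    lam1: float,
    lam2: float,
    width: int = 30,
) -> Tuple[np.ndarray, np.ndarray]:
    """Stage probabilities of a two-stage design by exhaustive enumeration.

    Enumerates the joint support of the two stage increments over a window
    of +/- ``width`` around their means (adequate for small n * lambda).
    """
    mu1, mu2 = n * lam1, n * lam2
    mean = int(round(mu1 - mu2))
    grid = np.arange(mean - width, mean + width + 1)
    g = np.array([poisson_convolution_pmf(int(t), mu1, mu2, jmax=width + 60) for t in grid])
    A = np.zeros(2)
    R = np.zeros(2)
    for t1, p1 in zip(grid, g):
        if t1 >= r[0]:
            R[0] += p1
        elif t1 < a[0]:
            A[0] += p1
        else:
            for d, p2 in zip(grid, g):
                t2 = t1 + d
                if t2 >= r[1]:
                    R[1] += p1 * p2
                else:
                    A[1] += p1 * p2
    return A, R


def _sk_cdf(t: int, mu1: float, mu2: float) -> float:
    return float(stats.skellam.cdf(t, mu1, mu2))


def _sk_sf(t: int, mu1: float, mu2: float) -> float:
    return float(stats.skellam.sf(t, mu1, mu2))


def brute_force_k2_search(
    lam: float,
    delta: float,
    alpha: float,
    beta: float,
    lam_ess: float,
    eps: float,
    n_fixed: int,
    n_max_factor: float = 1.5,
) -> Optional[Dict[str, object]]:
    """Plain-loop optimal two-stage search for a point-hypothesis problem.

    Minimizes the null ESS over all (n, a1, r1, a2 = r2) in the
    epsilon-bounded boundary box, with the final boundary taken as the
    smallest integer controlling the type-I error.  Ties break on smaller
    maximal sample size, then n, then (a1, r1).  All probabilities come from
    ``scipy.stats.skellam`` lookup tables.
    """
    best: Optional[Dict[str, object]] = None
    for n in range(1, int(math.floor(n_max_factor * n_fixed)) + 1):
        mu0 = n * lam
        a_star = next(aa for aa in range(int(mu0), -10 * n - 200, -1) if _sk_cdf(aa - 1, mu0, mu0) <= eps)
        mu1a, mu2a = n * lam, n * (lam - delta)
        r_star = next(rr for rr in range(int(round(mu1a - mu2a)), 20 * n + 400) if _sk_sf(rr - 1, mu1a, mu2a) <= eps)
        if r_star - a_star < 2:
            continue
        tlo, thi = 2 * a_star - r_star - 2, 2 * r_star + 2
        grid = np.arange(tlo, thi + 1)
        g0 = stats.skellam.pmf(grid, mu0, mu0)
        sf0 = stats.skellam.sf(grid, mu0, mu0)
        g1 = stats.skellam.pmf(grid, mu1a, mu2a)
        cdf1 = stats.skellam.cdf(grid, mu1a, mu2a)
        mue = n * lam_ess
        cdf_e = stats.skellam.cdf(grid, mue, mue)
        sf_e = stats.skellam.sf(grid, mue, mue)

        def ix(t):
            return t - tlo

        for a1 in range(a_star, r_star - 1):
            for r1 in range(a1 + 2, r_star + 1):
                ts = np.arange(a1, r1)
                w0 = g0[ix(a1) : ix(r1)]
                w1 = g1[ix(a1) : ix(r1)]
                c_found = None
                for c in range(a1 + a_star, r1 + r_star + 1):
                    err1 = sf0[ix(r1 - 1)] + float(np.sum(w0 * sf0[(c - 1 - ts) - tlo]))
                    if err1 <= alpha + 1e-12:
                        c_found = c
                        break
                if c_found is None:
                    continue
                err2 = cdf1[ix(a1 - 1)] + float(np.sum(w1 * cdf1[(c_found - 1 - ts) - tlo]))
                if err2 > beta + 1e-12:
                    continue
                p1 = cdf_e[ix(a1 - 1)] + sf_e[ix(r1 - 1)]
                score = 2 * n * (2 - p1)
                key = (score, 4 * n, n, a1, r1)
                if best is None or key < best["key"]:
                    best = {"key": key, "n": n, "a": (a1, c_found), "r": (r1, c_found), "score": score}
    return best
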