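"""One-dimensional maximization over a closed rate interval.

Stopping probabilities of the exact engine have no known simple pattern in
the shared rate, so maxima are located with a multi-start strategy: a
21-point equispaced scan (endpoints included) followed by bounded Brent
refinement in the best bracketing subinterval, to absolute tolerance 1e-6 in
the rate.
"""

from __future__ import annotations

from typing import Callable, Tuple

import numpy as np
from scipy import optimize

__all__ = ["interval_max", "max_at_most", "smallest_int_where", "largest_int_where"]

_GRID_POINTS = 21
_XATOL = 1e-6


def interval_max(
    f: Callable[[float], float],
    lo: float,
    hi: float,
    grid_points: int = _GRID_POINTS,
    xatol: float = _XATOL,
) -> Tuple[float, float]:
    """Return ``(max f, argmax)`` over the closed interval ``[lo, hi]``.

    A degenerate interval is evaluated directly without any search.
    """
    if lo == hi:
        return f(lo), lo
    xs = np.linspace(lo, hi, grid_points)
    ys = np.array([f(x) for x in xs])
    i = int(np.argmax(ys))
    best_x, best_y = float(xs[i]), float(ys[i])
    blo = float(xs[max(i - 1, 0)])
    bhi = float(xs[min(i + 1, grid_points - 1)])
    res = optimize.minimize_scalar(
        lambda x: -f(x), bounds=(blo, bhi), method="bounded", options={"xatol": xatol}
    )
    if res.success and -res.fun > best_y:
        best_x, best_y = float(res.x), float(-res.fun)
    return best_y, best_x


def max_at_most(
    f: Callable[[float], float],
    lo: float,
    hi: float,
    threshold: float,
    grid_points: int = _GRID_POINTS,
) -> bool:
    """Decide whether ``max f <= threshold`` over ``[lo, hi]``.

    Consistent with :func:`interval_max` (same grid and refinement), but the
    grid scan exits early once any value exceeds the threshold.
    """
    if lo == hi:
        return f(lo) <= threshold
    xs = np.linspace(lo, hi, grid_points)
    for x in xs:
        if f(x) > threshold:
            return False
    value, _ = interval_max(f, lo, hi, grid_points=grid_points)
    return value <= threshold


def _bracket_predicate(
    pred: Callable[[int], bool], start: int, step: int, increasing: bool, max_steps: int = 300
) -> Tuple[int, int]:
    """Bracket the switch point of a monotone integer predicate.

    For ``increasing`` predicates (False below, True above) returns
    ``(lo, hi)`` with ``pred(lo) == False`` and ``pred(hi) == True``.
    """
    x = start
    if increasing:
        if pred(x):
            hi = x
            lo = x - step
            for _ in range(max_steps):
                if not pred(lo):
                    return lo, hi
                hi = lo
                step *= 2
                lo -= step
            raise RuntimeError("failed to bracket predicate (downward)")
        lo = x
        hi = x + step
        for _ in range(max_steps):
            if pred(hi):
                return lo, hi
            lo = hi
            step *= 2
            hi += step
        raise RuntimeError("failed to bracket predicate (upward)")
    # decreasing predicate: flip
    lo, hi = _bracket_predicate(lambda v: not pred(v), start, step, increasing=True, max_steps=max_steps)
    return lo, hi


def smallest_int_where(pred: Callable[[int], bool], start: int, step: int = 8) -> int:
    """Smallest integer ``x`` with ``pred(x)`` true, for ``pred`` monotone
    nondecreasing in ``x`` (False then True)."""
    lo, hi = _bracket_predicate(pred, start, max(step, 1), increasing=True)
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if pred(mid):
            hi = mid
        else:
            lo = mid
    return hi


def largest_int_where(pred: Callable[[int], bool], start: int, step: int = 8) -> int:
    """Largest integer ``x`` with ``pred(x)`` true, for ``pred`` monotone
    nonincreasing in ``x`` (True then False)."""
    return -smallest_int_where(lambda v: pred(-v), -start, step)
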