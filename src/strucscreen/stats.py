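"""Unimodality testing for locus-length distributions.

A dip-type statistic: for every candidate mode position the empirical
cdf is compared against its greatest convex minorant to the left and
its least concave majorant to the right (a unimodal cdf is convex left
of the mode, concave right of it); the statistic is the smallest such
maximal deviation over all candidate modes.  The p-value is calibrated
by Monte Carlo against the uniform null, the standard calibration
distribution for dip tests.  Integer-valued samples (locus lengths) are
dithered with +/-0.5 uniform jitter so that ties do not create ecdf
cliffs absent from the continuous null.
"""

from __future__ import annotations

import numpy as np


def _cross(o, a, b) -> float:
    return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])


def _max_dev_lower_hull(x: np.ndarray, y: np.ndarray) -> float:
    """Max deviation of points above their greatest convex minorant."""
    hull: list[tuple[float, float]] = []
    for p in zip(x, y):
        while len(hull) >= 2 and _cross(hull[-2], hull[-1], p) <= 0:
            hull.pop()
        hull.append(p)
    dev = 0.0
    h = 0
    for px, py in zip(x, y):
        while h + 1 < len(hull) and hull[h + 1][0] < px:
            h += 1
        if h + 1 < len(hull):
            (x0, y0), (x1, y1) = hull[h], hull[h + 1]
            base = y0 + (y1 - y0) * (px - x0) / (x1 - x0) if x1 > x0 else y0
        else:
            base = hull[-1][1]
        dev = max(dev, py - base)
    return dev


def _dip_of_sorted(x: np.ndarray, n_modes: int) -> float:
    n = len(x)
    y = (np.arange(n) + 1.0) / n
    candidates = np.unique(np.linspace(0, n - 1, min(n, n_modes)).astype(int))
    best = np.inf
    for k in candidates:
        left = _max_dev_lower_hull(x[: k + 1], y[: k + 1])
        # concave majorant on the right == convex minorant of the
        # point-reflected cdf
        right = _max_dev_lower_hull(-x[k:][::-1], -y[k:][::-1])
        best = min(best, max(left, right))
    return float(best)


def dip_statistic(
    values, n_modes: int = 50, jitter: float = 0.5, seed: int = 0
) -> float:
    """Departure from unimodality of a 1-d sample (0 = perfectly
    unimodal-compatible up to ecdf step noise).  Ties are dithered
    within +/-*jitter* (seeded) before sorting."""
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 4:
        return 0.0
    if jitter > 0:
        rng = np.random.default_rng(seed)
        x = x + rng.uniform(-jitter, jitter, size=n)
    return _dip_of_sorted(np.sort(x), n_modes)


def dip_test(
    values,
    n_boot: int = 200,
    seed: int = 0,
    n_modes: int = 50,
    jitter: float = 0.5,
) -> tuple[float, float]:
    """(statistic, p) with the null distribution simulated from uniform
    samples of the same size."""
    stat = dip_statistic(values, n_modes=n_modes, jitter=jitter, seed=seed)
    n = len(values)
    rng = np.random.default_rng(seed + 1)
    null = np.array(
        [
            _dip_of_sorted(np.sort(rng.random(n)), n_modes)
            for _ in range(n_boot)
        ]
    )
    p = (1.0 + np.sum(null >= stat)) / (n_boot + 1.0)
    return stat, float(p)
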