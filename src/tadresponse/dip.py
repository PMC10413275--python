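"""Hartigan & Hartigan's dip statistic for unimodality, from scratch.

The dip of a distribution function F is the smallest sup-norm distance
between F and the class of unimodal distribution functions (convex on
(-inf, mode], concave on [mode, +inf)). Large dips indicate at least two
modes. Here it is used on the distribution of TAD scores, which is
expected to be bimodal (mass near 0 and near 1) when coregulator gains and
losses are regionalized.

Algorithm
---------
The greatest-convex-minorant / least-concave-majorant (GCM/LCM) procedure
on the sorted sample: maintain a shrinking candidate modal interval
``[low, high]``; at each pass fit the GCM and LCM of the empirical CDF over
the interval, locate the largest gap between the two fits (the best
achievable fit error inside), harvest the one-sided deviations of the ECDF
from the hulls in the parts that leave the interval, and stop when the
interior gap no longer exceeds the deviation already found. The final
statistic is half the maximal deviation, in probability units.

For an empirical CDF of a sample with at least two distinct values the dip
is at least ``1/(2n)`` (a single jump of height 1/n can be approximated no
better than half its height); a constant sample is itself unimodal and has
dip 0.

The Monte Carlo p-value (:func:`dip_test`) compares the observed dip with
dips of uniform(0, 1) samples of the same size — the asymptotically least
favourable unimodal null — using the add-one estimator
``(exceedances + 1) / (n_null + 1)``, which is reproducible from a seed and
bounded below by ``1/(n_null + 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["DipResult", "dip_statistic", "dip_test"]


@dataclass(frozen=True)
class DipResult:
    dip: float
    p_value: float
    n: int
    n_null: int
    seed: int

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError("p_value must be in (0, 1]")


def _gcm_indices(x: np.ndarray, low: int, high: int) -> list[int]:
    """Touchpoints (ascending) of the greatest convex minorant of the points
    ``(x[i], i)`` for ``i`` in ``[low, high]`` — a lower convex hull."""
    hull = [low]
    for j in range(low + 1, high + 1):
        # pop while the previous touchpoint lies on or above the chord
        while len(hull) >= 2:
            a, b = hull[-2], hull[-1]
            if (x[j] - x[b]) * (b - a) < (x[b] - x[a]) * (j - b):
                break
            hull.pop()
        hull.append(j)
    return hull


def _lcm_indices(x: np.ndarray, low: int, high: int) -> list[int]:
    """Touchpoints (ascending) of the least concave majorant of ``(x[i], i)``."""
    hull = [high]
    for j in range(high - 1, low - 1, -1):
        while len(hull) >= 2:
            a, b = hull[-2], hull[-1]
            if (x[j] - x[b]) * (b - a) < (x[b] - x[a]) * (j - b):
                break
            hull.pop()
        hull.append(j)
    hull.reverse()
    return hull


def _max_hull_gap(
    x: np.ndarray, gcm: list[int], lcm: list[int]
) -> tuple[float, int, int]:
    """Largest vertical gap between the LCM fit (through ``(x[i], i + 1)``)
    and the GCM fit (through ``(x[i], i)``), located by walking both
    touchpoint lists bottom-up.

    Returns ``(gap, new_low, new_high)`` where the gap is attained between
    sample indices ``new_low`` and ``new_high``.
    """
    lg, ll = len(gcm), len(lcm)
    d = 0.0
    new_low, new_high = gcm[0], lcm[-1]
    a, b = 1, 1  # index of current gcm touchpoint / lcm touchpoint
    while True:
        ga, lb = gcm[a], lcm[b]
        if ga > lb:
            # LCM touchpoint lb falls inside the GCM segment [gcm[a-1], ga]
            g0 = gcm[a - 1]
            gap = (lb - g0 + 1) - (x[lb] - x[g0]) * (ga - g0) / (x[ga] - x[g0])
            if gap >= d:
                d, new_low, new_high = gap, g0, lb
            b += 1
        else:
            # GCM touchpoint ga falls inside the LCM segment [lcm[b-1], lb]
            l0 = lcm[b - 1]
            gap = (x[ga] - x[l0]) * (lb - l0) / (x[lb] - x[l0]) - (ga - l0 - 1)
            if gap >= d:
                d, new_low, new_high = gap, ga, lb
            a += 1
        if a > lg - 1:
            a = lg - 1
        if b > ll - 1:
            b = ll - 1
        if gcm[a] == lcm[b]:
            break
    return d, new_low, new_high


def _gcm_tail_deviation(x: np.ndarray, gcm: list[int], stop: int) -> float:
    """Max deviation of the ECDF (post-jump values ``i + 1``) above the GCM
    fit, over GCM segments whose upper end is at most ``stop``."""
    best = 1.0
    for a in range(1, len(gcm)):
        jb, je = gcm[a - 1], gcm[a]
        if je > stop:
            break
        if je - jb > 1 and x[je] != x[jb]:
            slope = (je - jb) / (x[je] - x[jb])
            j = np.arange(jb + 1, je)
            t = (j - jb + 1) - (x[j] - x[jb]) * slope
            m = float(t.max())
            if m > best:
                best = m
    return best


def _lcm_tail_deviation(x: np.ndarray, lcm: list[int], start: int) -> float:
    """Max deviation of the ECDF (pre-jump values ``i``) below the LCM fit,
    over LCM segments whose lower end is at least ``start``."""
    best = 1.0
    for a in range(len(lcm) - 1, 0, -1):
        jb, je = lcm[a - 1], lcm[a]
        if jb < start:
            break
        if je - jb > 1 and x[je] != x[jb]:
            slope = (je - jb) / (x[je] - x[jb])
            j = np.arange(jb + 1, je)
            t = (x[j] - x[jb]) * slope - (j - jb - 1)
            m = float(t.max())
            if m > best:
                best = m
    return best


def dip_statistic(sample: Sequence[float]) -> float:
    """The dip of the empirical distribution of ``sample``.

    Requires at least two observations. Invariant under increasing affine
    transforms of the sample; at least ``1/(2n)`` whenever the sample has
    two distinct values; 0 for a constant sample.
    """
    x = np.sort(np.asarray(sample, dtype=float))
    n = x.size
    if n < 2:
        raise ValueError(f"dip_statistic: need n >= 2 observations, got {n}")
    if not np.all(np.isfinite(x)):
        raise ValueError("dip_statistic: sample contains non-finite values")
    if x[0] == x[-1]:
        return 0.0

    low, high = 0, n - 1
    d_count = 1.0  # running max deviation, in count units (2n * dip)
    while True:
        gcm = _gcm_indices(x, low, high)
        lcm = _lcm_indices(x, low, high)
        if len(gcm) == 2 and len(lcm) == 2:
            # ECDF is both convex and concave on [low, high]: the hulls are
            # a single parallel band of height one jump; nothing inside can
            # exceed the floor already accounted for.
            break
        d, new_low, new_high = _max_hull_gap(x, gcm, lcm)
        if d <= d_count:
            break
        left = _gcm_tail_deviation(x, gcm, new_low)
        right = _lcm_tail_deviation(x, lcm, new_high)
        d_count = max(d_count, left, right)
        if new_low == low and new_high == high:
            break
        low, high = new_low, new_high
    return d_count / (2 * n)


def dip_test(sample: Sequence[float], n_null: int = 9_999, seed: int = 0) -> DipResult:
    """Monte Carlo dip test of unimodality against uniform(0, 1) nulls.

    ``p = (#{null dips >= observed} + 1) / (n_null + 1)``; deterministic
    given ``seed``. Sample size must be at least 4 (below that the dip is
    pinned at its floor and the test is vacuous); at least 999 null
    replicates are recommended for a resolvable p-value.
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 4:
        raise ValueError(f"dip_test: need n >= 4, got {x.size}")
    if n_null < 1:
        raise ValueError("dip_test: n_null must be >= 1")
    observed = dip_statistic(x)
    rng = np.random.default_rng(seed)
    nulls = rng.random((n_null, x.size))
    exceed = sum(dip_statistic(row) >= observed for row in nulls)
    p = (exceed + 1) / (n_null + 1)
    return DipResult(observed, p, int(x.size), int(n_null), int(seed))
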