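"""Brute-force dip oracle, independent of the GCM/LCM algorithm under test.

The dip of a distribution F — the smallest sup-norm distance from F to the
class of unimodal distribution functions — equals half the maximal excess
mass difference ``max_lambda [E_2(lambda) - E_1(lambda)]``, where
``E_k(lambda)`` is the largest value of ``F(C) - lambda * |C|`` over unions
of k disjoint closed intervals (Muller & Sawitzki's excess-mass functional;
the two-interval gain over one interval measures exactly how far F is from
unimodality).

For an empirical distribution both envelopes are upper envelopes of
finitely many lines in lambda (one line per candidate interval or interval
pair, with endpoints at distinct sample values), so their difference is
piecewise linear and the maximum is attained either at lambda = 0, at a
crossing of two lines from either family, or on the flat tail beyond all
crossings. Enumerating every candidate interval, pair and crossing gives
the dip exactly — O(m^8) in the number of distinct values, fine for the
small-n battery.

A direct minimisation over unimodal CDFs is *not* used because it is not a
finite linear program: when the mode falls strictly between two sample
points, convexity to its left and concavity to its right couple the
straddling segment through a slope x width product (verified by hand to be
binding on 5-point samples).
"""

from __future__ import annotations

import numpy as np


def dip_bruteforce(sample) -> float:
    x = np.sort(np.asarray(sample, dtype=float))
    n = x.size
    if n < 2:
        raise ValueError("need n >= 2")
    values, counts = np.unique(x, return_counts=True)
    m = values.size
    if m == 1:
        return 0.0
    cum0 = np.concatenate([[0.0], np.cumsum(counts) / n])

    # single-interval lines (mass, width), plus the empty set
    singles = [(0.0, 0.0)]
    for i in range(m):
        for j in range(i, m):
            singles.append((cum0[j + 1] - cum0[i], values[j] - values[i]))
    # pair lines: disjoint [i..j], [k..l] with j < k; E2 >= E1 via singles
    pairs = list(singles)
    for i in range(m):
        for j in range(i, m):
            for k in range(j + 1, m):
                for l in range(k, m):
                    # parenthesised per interval: adding a tiny width to a
                    # large one then subtracting must not absorb it to zero
                    pairs.append(
                        (
                            (cum0[j + 1] - cum0[i]) + (cum0[l + 1] - cum0[k]),
                            (values[j] - values[i]) + (values[l] - values[k]),
                        )
                    )
    s1 = np.unique(np.array(singles), axis=0)
    s2 = np.unique(np.array(pairs), axis=0)

    def crossings(lines: np.ndarray) -> np.ndarray:
        mass, width = lines[:, 0], lines[:, 1]
        dm = mass[:, None] - mass[None, :]
        dw = width[:, None] - width[None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            lam = np.where(dw != 0, dm / dw, np.nan)
        lam = lam[np.isfinite(lam)]
        return lam[lam >= 0]

    cand = np.concatenate([[0.0], crossings(s1), crossings(s2)])
    cand = np.unique(np.concatenate([cand, [cand.max() + 1.0]]))
    with np.errstate(over="ignore"):  # huge lambda x width -> -inf, never the max
        e1 = (s1[:, 0][None, :] - cand[:, None] * s1[:, 1][None, :]).max(axis=1)
        e2 = (s2[:, 0][None, :] - cand[:, None] * s2[:, 1][None, :]).max(axis=1)
    return float((e2 - e1).max() / 2.0)
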