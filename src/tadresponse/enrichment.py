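"""The statistical battery: Fisher, chi-squared with Pearson residuals,
the gene-in-responsive-TAD permutation test, Mann-Whitney time-course
comparisons and Benjamini-Hochberg correction.

Conventions chosen for auditability:

* No Yates continuity correction for chi-squared, so that the statistic
  equals the sum of squared Pearson residuals exactly (the identity the
  association plot relies on).
* The Fisher odds ratio is the sample cross-product ``(a d)/(b c)``
  (reported as ``inf`` when ``b c = 0``, with the Haldane-Anscombe
  +0.5-corrected value alongside); exact conditional-MLE odds ratios from
  other environments differ slightly, the p-value does not.
* All Monte Carlo p-values use the add-one estimator
  ``(exceedances + 1) / (n + 1)``, reproducible from a seed and bounded
  below by ``1/(n + 1)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ContingencyTable",
    "PermutationResult",
    "ChiSquareResult",
    "fisher_2x2",
    "chisq_with_residuals",
    "permutation_gene_tad_enrichment",
    "mann_whitney_u",
    "bh_adjust",
    "significance_stars",
    "timecourse_comparison",
]

#: Pearson residuals beyond this absolute value flag a cell as enriched
#: (positive) or depleted (negative).
RESIDUAL_CUTOFF = 2.0


@dataclass(frozen=True)
class ContingencyTable:
    """Labelled matrix of non-negative integer counts (at least 2x2)."""

    rows: tuple[str, ...]
    cols: tuple[str, ...]
    counts: tuple[tuple[int, ...], ...]

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
            raise ValueError("contingency table must be at least 2x2")
        if arr.shape != (len(self.rows), len(self.cols)):
            raise ValueError("label/count shape mismatch")
        if (arr < 0).any():
            raise ValueError("negative counts")
        if not np.issubdtype(arr.dtype, np.integer):
            raise ValueError("counts must be integers")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ContingencyTable":
        return cls(
            tuple(str(r) for r in df.index),
            tuple(str(c) for c in df.columns),
            tuple(tuple(int(v) for v in row) for row in df.to_numpy()),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            np.asarray(self.counts), index=list(self.rows), columns=list(self.cols)
        )

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.counts)


def fisher_2x2(table: ContingencyTable) -> dict:
    """Fisher's exact test on a 2x2 table.

    Returns a dict with the sample ``odds_ratio`` (``inf`` when the
    cross-product denominator is zero), ``odds_ratio_haldane`` (+0.5 in
    every cell), and the exact two-sided ``p_value`` (sum of
    hypergeometric probabilities no larger than the observed table's).
    """
    arr = table.array
    if arr.shape != (2, 2):
        raise ValueError(f"fisher_2x2: need a 2x2 table, got {arr.shape}")
    a, b = int(arr[0, 0]), int(arr[0, 1])
    c, d = int(arr[1, 0]), int(arr[1, 1])
    _, p = stats.fisher_exact(arr, alternative="two-sided")
    odds = math.inf if b * c == 0 else (a * d) / (b * c)
    haldane = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    return {
        "odds_ratio": odds,
        "odds_ratio_haldane": haldane,
        "p_value": float(p),
    }


@dataclass(frozen=True)
class ChiSquareResult:
    chi2: float
    df: int
    p_value: float
    expected: pd.DataFrame
    residuals: pd.DataFrame

    def flags(self, cutoff: float = RESIDUAL_CUTOFF) -> pd.DataFrame:
        """"enriched" / "depleted" / "" per cell at |residual| > cutoff."""
        res = self.residuals.to_numpy()
        out = np.where(res > cutoff, "enriched", np.where(res < -cutoff, "depleted", ""))
        return pd.DataFrame(out, index=self.residuals.index, columns=self.residuals.columns)

    def to_long_frame(self, cutoff: float = RESIDUAL_CUTOFF) -> pd.DataFrame:
        """Association-plot data: one row per cell with observed, expected,
        residual and the enrichment flag."""
        flags = self.flags(cutoff)
        rows = []
        obs = self.expected  # same index/columns as residuals
        for r in self.residuals.index:
            for c in self.residuals.columns:
                rows.append(
                    {
                        "row": r,
                        "col": c,
                        "expected": self.expected.loc[r, c],
                        "residual": self.residuals.loc[r, c],
                        "flag": flags.loc[r, c],
                    }
                )
        return pd.DataFrame(rows)


def chisq_with_residuals(table: ContingencyTable) -> ChiSquareResult:
    """Pearson chi-squared test (no continuity correction) with residuals.

    ``chi2 = sum (O - E)^2 / E`` with expectations from the margins;
    ``residual = (O - E) / sqrt(E)`` so that ``chi2`` equals the sum of
    squared residuals. Raises on a zero row/column margin (expected counts
    must all be positive).
    """
    obs = table.array.astype(float)
    row_m = obs.sum(axis=1)
    col_m = obs.sum(axis=0)
    if (row_m == 0).any() or (col_m == 0).any():
        raise ValueError("chisq_with_residuals: zero margin")
    expected = np.outer(row_m, col_m) / obs.sum()
    residuals = (obs - expected) / np.sqrt(expected)
    chi2 = float((residuals**2).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(stats.chi2.sf(chi2, df))
    idx, cols = list(table.rows), list(table.cols)
    return ChiSquareResult(
        chi2,
        df,
        p,
        pd.DataFrame(expected, index=idx, columns=cols),
        pd.DataFrame(residuals, index=idx, columns=cols),
    )


@dataclass(frozen=True)
class PermutationResult:
    observed: int
    n_perm: int
    exceedances: int
    p_value: float
    seed: int

    def __post_init__(self) -> None:
        expected_p = (self.exceedances + 1) / (self.n_perm + 1)
        if abs(self.p_value - expected_p) > 1e-12:
            raise ValueError("p_value inconsistent with add-one estimator")


def permutation_gene_tad_enrichment(
    query_genes: Iterable[str],
    universe: Iterable[str],
    gene_tad: Mapping[str, str],
    responsive_tads: Iterable[str],
    n_perm: int = 10_000,
    seed: int = 0,
    shuffle: str = "genes",
) -> PermutationResult:
    """Permutation test: are query genes concentrated in responsive TADs?

    The statistic is the number of query genes whose TAD is responsive
    (up or down). The null resamples, ``n_perm`` times, gene sets of size
    ``|query|`` uniformly without replacement from ``universe``
    (``shuffle="genes"``, the default) or permutes the responsive labels
    over the distinct TADs of the universe, preserving the gene-TAD
    clustering structure (``shuffle="tads"``).

    ``p = (#{null >= observed} + 1) / (n_perm + 1)``; deterministic given
    ``seed``; the smallest attainable p is ``1/(n_perm + 1)``.
    """
    query = sorted(set(query_genes))
    uni = sorted(set(universe))
    if not query:
        raise ValueError("permutation test: empty query set")
    if n_perm < 1:
        raise ValueError("permutation test: n_perm must be >= 1")
    if not set(query) <= set(uni):
        extra = sorted(set(query) - set(uni))[:5]
        raise ValueError(f"query genes outside the universe, e.g. {extra}")
    if shuffle not in ("genes", "tads"):
        raise ValueError(f"unknown shuffle mode {shuffle!r}")
    responsive = set(responsive_tads)

    tads_of = [gene_tad.get(g) for g in uni]
    indicator = np.array([t in responsive for t in tads_of], dtype=np.int8)
    query_set = set(query)
    in_query = np.array([g in query_set for g in uni], dtype=bool)
    observed = int(indicator[in_query].sum())

    rng = np.random.default_rng(seed)
    k = len(query)
    if shuffle == "genes":
        # The statistic of a uniform without-replacement draw of k genes
        # from a universe with K responsive-TAD genes is exactly
        # hypergeometric(K, N - K, k); sampling it directly is the same
        # null, without materialising each permutation.
        n_responsive = int(indicator.sum())
        draws = rng.hypergeometric(
            n_responsive, len(uni) - n_responsive, k, size=n_perm
        )
    else:
        distinct = sorted({t for t in tads_of if t is not None})
        resp_vec = np.array([t in responsive for t in distinct], dtype=np.int8)
        tad_index = {t: i for i, t in enumerate(distinct)}
        query_tads = [t for t, q in zip(tads_of, in_query) if q and t is not None]
        gene_tad_idx = np.array([tad_index[t] for t in query_tads], dtype=int)
        perms = np.stack([rng.permutation(resp_vec) for _ in range(n_perm)])
        draws = perms[:, gene_tad_idx].sum(axis=1)
    exceed = int((draws >= observed).sum())
    p = (exceed + 1) / (n_perm + 1)
    return PermutationResult(observed, int(n_perm), exceed, float(p), int(seed))


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact enumeration when both samples have at most 8 observations and
    there are no ties; otherwise the normal approximation with tie and
    continuity corrections. Returns ``(U of x, two-sided p)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("mann_whitney_u: empty group")
    no_ties = np.unique(np.concatenate([x, y])).size == x.size + y.size
    method = "exact" if (x.size <= 8 and y.size <= 8 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjustment, aligned to input order."""
    arr = np.asarray(pvalues, dtype=float)
    if arr.size == 0:
        return []
    if ((arr < 0) | (arr > 1)).any() or np.isnan(arr).any():
        raise ValueError("bh_adjust: p-values must be in [0, 1]")
    _, adjusted, _, _ = multipletests(arr, method="fdr_bh")
    return [float(v) for v in adjusted]


def significance_stars(p: float) -> str:
    """Figure-legend star encoding: ns / * < 0.05 / ** < 0.01 / *** < 0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def timecourse_comparison(
    group_a: Mapping[str, Mapping[float, float]] | pd.DataFrame,
    group_b: Mapping[str, Mapping[float, float]] | pd.DataFrame,
    timepoints: Sequence[float] = (0.5, 1, 2, 3, 4, 5, 6),
) -> pd.DataFrame:
    """Per-timepoint Mann-Whitney comparison of two gene groups' log2FC.

    Accepts gene -> {timepoint: log2fc} mappings or DataFrames indexed by
    gene with timepoint columns. One test per timepoint, BH correction
    across the timepoints, star encoding per the figure legends.
    """

    def _to_frame(g) -> pd.DataFrame:
        if isinstance(g, pd.DataFrame):
            return g
        return pd.DataFrame.from_dict(g, orient="index")

    fa, fb = _to_frame(group_a), _to_frame(group_b)
    raws, stats_u, ns = [], [], []
    for t in timepoints:
        if t not in fa.columns or t not in fb.columns:
            raise ValueError(f"timecourse_comparison: no data at {t} h")
        xa = fa[t].dropna().to_numpy()
        xb = fb[t].dropna().to_numpy()
        if xa.size == 0 or xb.size == 0:
            raise ValueError(f"timecourse_comparison: empty group at {t} h")
        u, p = mann_whitney_u(xa, xb)
        raws.append(p)
        stats_u.append(u)
        ns.append((xa.size, xb.size))
    adjusted = bh_adjust(raws)
    return pd.DataFrame(
        {
            "timepoint": list(timepoints),
            "U": stats_u,
            "n_a": [n[0] for n in ns],
            "n_b": [n[1] for n in ns],
            "p_value": raws,
            "p_adjusted": adjusted,
            "stars": [significance_stars(p) for p in adjusted],
        }
    )
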