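"""Gene response calls from per-timepoint differential-expression tables.

A gene assayed over a 0.5-6 h hormone time course is called *activated* if
at any single timepoint it is both significant (BH-adjusted p below alpha)
and strongly induced (log2 fold change above ``lfc_up``); *repressed*
symmetrically below ``lfc_down``; *inactive* when an optional read-count
activity filter fails (fewer than ``active_fraction`` of samples with at
least ``min_reads`` reads), in which case the gene is excluded from all
downstream analyses; otherwise *unchanged*.

Significance and fold change must coincide in the same row (same
timepoint): a gene significant at 1 h and strongly induced only at 4 h is
not called. Genes qualifying in both directions across the time course are
resolved by majority of qualifying timepoints, ties by the larger maximum
absolute fold change, and flagged ambiguous.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TimepointDE",
    "GeneCallConfig",
    "GeneResponse",
    "classify_gene",
    "classify_table",
    "cohort_summary",
    "trajectory_summary",
]

CALLS = ("activated", "repressed", "unchanged", "inactive")


@dataclass(frozen=True)
class TimepointDE:
    """One gene x timepoint differential-expression row (vs the 0 h baseline)."""

    gene_id: str
    timepoint: float
    log2fc: float
    padj: float | None = None

    def __post_init__(self) -> None:
        if self.timepoint <= 0:
            raise ValueError(
                f"{self.gene_id}: timepoint must be > 0 h (fold changes are "
                "relative to the 0 h baseline)"
            )
        if self.padj is not None and not math.isnan(self.padj):
            if not (0.0 <= self.padj <= 1.0):
                raise ValueError(f"{self.gene_id}: padj {self.padj} outside [0, 1]")


@dataclass(frozen=True)
class GeneCallConfig:
    """Thresholds for the activated/repressed/inactive calls.

    Defaults: |log2FC| > 0.75 with BH-adjusted p < 0.05 at some timepoint;
    active when >= 1 read in 60% of samples.
    """

    lfc_up: float = 0.75
    lfc_down: float = -0.75
    alpha: float = 0.05
    active_fraction: float = 0.6
    min_reads: int = 1

    def __post_init__(self) -> None:
        if not (self.lfc_up > 0 > self.lfc_down):
            raise ValueError("require lfc_up > 0 > lfc_down")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if not (0 < self.active_fraction <= 1):
            raise ValueError("active_fraction must be in (0, 1]")


@dataclass(frozen=True)
class GeneResponse:
    gene_id: str
    call: str
    trajectory: tuple[tuple[float, float], ...]
    ambiguous: bool = False

    def __post_init__(self) -> None:
        if self.call not in CALLS:
            raise ValueError(f"unknown call {self.call!r}")
        times = [t for t, _ in self.trajectory]
        if times != sorted(times):
            raise ValueError(f"{self.gene_id}: trajectory not sorted by timepoint")

    def log2fc_at(self, timepoint: float) -> float | None:
        for t, v in self.trajectory:
            if t == timepoint:
                return v
        return None


def _is_significant(padj: float | None, alpha: float) -> bool:
    # Missing padj (NA from upstream independent filtering) is non-significant.
    return padj is not None and not math.isnan(padj) and padj < alpha


def classify_gene(
    rows: Sequence[TimepointDE],
    counts: Sequence[float] | None = None,
    config: GeneCallConfig = GeneCallConfig(),
) -> GeneResponse:
    """Call one gene from its timepoint rows and optional per-sample counts.

    ``counts`` are raw read counts across all samples of the time course;
    when omitted the activity filter is skipped. Deterministic and
    invariant to row order.
    """
    if not rows:
        raise ValueError("classify_gene: no rows")
    gene_ids = {r.gene_id for r in rows}
    if len(gene_ids) > 1:
        raise ValueError(f"classify_gene: mixed gene_ids {sorted(gene_ids)}")
    gene_id = rows[0].gene_id
    rows = sorted(rows, key=lambda r: r.timepoint)
    trajectory = tuple((r.timepoint, r.log2fc) for r in rows)

    if counts is not None:
        counts = list(counts)
        if not counts:
            raise ValueError(f"{gene_id}: empty counts vector")
        frac = sum(c >= config.min_reads for c in counts) / len(counts)
        if frac < config.active_fraction:
            return GeneResponse(gene_id, "inactive", trajectory)

    up = [
        r
        for r in rows
        if _is_significant(r.padj, config.alpha) and r.log2fc > config.lfc_up
    ]
    down = [
        r
        for r in rows
        if _is_significant(r.padj, config.alpha) and r.log2fc < config.lfc_down
    ]
    if up and down:
        # Both directions qualify somewhere in the time course: majority of
        # qualifying timepoints wins, tie broken by the larger |log2fc|.
        if len(up) != len(down):
            call = "activated" if len(up) > len(down) else "repressed"
        else:
            call = (
                "activated"
                if max(r.log2fc for r in up) >= max(-r.log2fc for r in down)
                else "repressed"
            )
        return GeneResponse(gene_id, call, trajectory, ambiguous=True)
    if up:
        return GeneResponse(gene_id, "activated", trajectory)
    if down:
        return GeneResponse(gene_id, "repressed", trajectory)
    return GeneResponse(gene_id, "unchanged", trajectory)


def classify_table(
    de: pd.DataFrame,
    counts: pd.DataFrame | None = None,
    config: GeneCallConfig = GeneCallConfig(),
) -> list[GeneResponse]:
    """Vectorised :func:`classify_gene` over a long-format DE table.

    ``de`` needs columns ``gene_id, timepoint, log2fc, padj``; ``counts``
    is an optional gene x sample matrix indexed by gene_id. Genes present
    in ``counts`` but absent from ``de`` are ignored.
    """
    responses = []
    counts_index = None if counts is None else set(counts.index)
    for gene_id, group in de.groupby("gene_id", sort=True):
        rows = [
            TimepointDE(
                str(gene_id),
                float(r.timepoint),
                float(r.log2fc),
                None if pd.isna(r.padj) else float(r.padj),
            )
            for r in group.itertuples(index=False)
        ]
        gene_counts = None
        if counts is not None and gene_id in counts_index:
            gene_counts = counts.loc[gene_id].to_numpy()
        responses.append(classify_gene(rows, gene_counts, config))
    return responses


def cohort_summary(responses: Iterable[GeneResponse]) -> dict[str, int]:
    """Counts per call, plus the derived totals used throughout the analysis.

    ``regulated`` = activated + repressed; ``universe`` = everything except
    inactive (the background for enrichment tests).
    """
    out = {call: 0 for call in CALLS}
    for r in responses:
        out[r.call] += 1
    out["regulated"] = out["activated"] + out["repressed"]
    out["universe"] = sum(out[c] for c in ("activated", "repressed", "unchanged"))
    return out


def trajectory_summary(
    group: Sequence[GeneResponse],
    timepoints: Sequence[float],
) -> pd.DataFrame:
    """Per-timepoint mean log2FC, SEM and n for a group of genes.

    Genes missing a value at a requested timepoint are excluded there (the
    ``n_missing`` column reports how many). SEM = sd / sqrt(n) with the
    n-1 denominator for sd; a single observation yields SEM 0 with n = 1.
    """
    if not group:
        raise ValueError("trajectory_summary: empty group")
    records = []
    for t in timepoints:
        values = [v for v in (g.log2fc_at(t) for g in group) if v is not None]
        n = len(values)
        if n == 0:
            raise ValueError(f"trajectory_summary: no gene has a value at {t} h")
        arr = np.asarray(values, dtype=float)
        mean = float(arr.mean())
        sem = float(arr.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
        records.append(
            {
                "timepoint": t,
                "mean_log2fc": mean,
                "sem": sem,
                "n": n,
                "n_missing": len(group) - n,
            }
        )
    return pd.DataFrame.from_records(records)


def responses_to_frame(responses: Sequence[GeneResponse]) -> pd.DataFrame:
    """Wide table of calls and per-timepoint log2FC columns (``lfc_<t>h``)."""
    timepoints = sorted({t for r in responses for t, _ in r.trajectory})
    rows = []
    for r in responses:
        row: dict = {"gene_id": r.gene_id, "call": r.call, "ambiguous": r.ambiguous}
        for t in timepoints:
            row[f"lfc_{t:g}h"] = r.log2fc_at(t)
        rows.append(row)
    return pd.DataFrame.from_records(rows)
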