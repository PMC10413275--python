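"""TAD activity scoring and classification.

Each differential region is assigned to the TAD containing its midpoint;
per TAD, the score is ``gain / (gain + loss)`` over assigned regions. TADs
with at least one region are *scored*; scored TADs are classified *up*
(score >= 0.7), *down* (score <= 0.3) or *balanced* (strictly between).
Both boundaries are inclusive. TADs with no region are *unscored*.

Genes are assigned to TADs by TSS containment. Bimodality of the score
distribution is assessed with the dip statistic (see
:mod:`tadresponse.dip`, re-exported here).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import DifferentialRegion, Gene, Tad, validate_tads
from .dip import DipResult, dip_statistic, dip_test  # noqa: F401  (re-export)

__all__ = [
    "UNASSIGNED",
    "TadActivity",
    "assign_regions_to_tads",
    "assign_genes_to_tads",
    "score_tads",
    "classify_tads",
    "activities_to_frame",
    "DipResult",
    "dip_statistic",
    "dip_test",
]

#: Sentinel for regions/genes falling between TADs.
UNASSIGNED = "unassigned"

CATEGORIES = ("up", "balanced", "down", "unscored")


@dataclass(frozen=True)
class TadActivity:
    """Gain/loss census and score of one TAD.

    ``score`` is None (and ``category`` "unscored") when the TAD received
    no differential region.
    """

    tad_id: str
    n_gain: int
    n_loss: int
    score: float | None
    category: str = "unscored"

    def __post_init__(self) -> None:
        if self.n_gain < 0 or self.n_loss < 0:
            raise ValueError("negative gain/loss count")
        total = self.n_gain + self.n_loss
        if total == 0:
            if self.score is not None or self.category != "unscored":
                raise ValueError("TAD without regions must be unscored")
        elif self.score is None or abs(self.score - self.n_gain / total) > 1e-12:
            raise ValueError("score inconsistent with gain/(gain+loss)")
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


class _TadIndex:
    """Point-in-TAD lookup over sorted, non-overlapping TADs per chromosome."""

    def __init__(self, tads: Sequence[Tad]):
        validate_tads(tads)
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, list[str]]] = {}
        grouped: dict[str, list[Tad]] = {}
        for t in tads:
            grouped.setdefault(t.interval.chrom, []).append(t)
        for chrom, group in grouped.items():
            group.sort(key=lambda t: t.interval.start)
            starts = np.array([t.interval.start for t in group])
            ends = np.array([t.interval.end for t in group])
            ids = [t.tad_id for t in group]
            self._by_chrom[chrom] = (starts, ends, ids)

    def lookup(self, chrom: str, pos: int) -> str:
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return UNASSIGNED
        starts, ends, ids = entry
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        if i >= 0 and pos < ends[i]:
            return ids[i]
        return UNASSIGNED


def assign_regions_to_tads(
    regions: Sequence[DifferentialRegion],
    tads: Sequence[Tad],
) -> dict[str, str]:
    """Map region_id -> tad_id by midpoint containment (half-open).

    A region straddling a boundary belongs to the TAD containing
    ``floor((start + end) / 2)``; regions in inter-TAD gaps map to
    :data:`UNASSIGNED`.
    """
    index = _TadIndex(tads)
    return {
        r.region_id: index.lookup(r.interval.chrom, r.interval.midpoint)
        for r in regions
    }


def assign_genes_to_tads(genes: Sequence[Gene], tads: Sequence[Tad]) -> dict[str, str]:
    """Map gene_id -> tad_id by TSS containment (half-open)."""
    index = _TadIndex(tads)
    return {g.gene_id: index.lookup(g.chrom, g.tss) for g in genes}


def score_tads(
    assignment: Mapping[str, str],
    regions: Sequence[DifferentialRegion],
    tads: Sequence[Tad],
) -> list[TadActivity]:
    """Per-TAD gain/loss counts and score ``gain / (gain + loss)``.

    One :class:`TadActivity` per TAD, in input TAD order; gain + loss
    summed over all activities equals the number of assigned regions.
    Categories are left "unscored" here — apply :func:`classify_tads`.
    """
    direction = {r.region_id: r.direction for r in regions}
    gains: dict[str, int] = {t.tad_id: 0 for t in tads}
    losses: dict[str, int] = {t.tad_id: 0 for t in tads}
    for region_id, tad_id in assignment.items():
        if tad_id == UNASSIGNED:
            continue
        if tad_id not in gains:
            raise ValueError(f"assignment references unknown TAD {tad_id!r}")
        if direction[region_id] == "gain":
            gains[tad_id] += 1
        else:
            losses[tad_id] += 1
    out = []
    for t in tads:
        g, l = gains[t.tad_id], losses[t.tad_id]
        score = g / (g + l) if g + l else None
        out.append(TadActivity(t.tad_id, g, l, score))
    return out


def classify_tads(
    activities: Sequence[TadActivity],
    up_min: float = 0.7,
    down_max: float = 0.3,
) -> list[TadActivity]:
    """Set categories: up (score >= up_min), down (score <= down_max),
    balanced in between; unscored TADs stay unscored."""
    if not up_min > down_max:
        raise ValueError("require up_min > down_max")
    out = []
    for a in activities:
        if a.score is None:
            out.append(replace(a, category="unscored"))
        elif a.score >= up_min:
            out.append(replace(a, category="up"))
        elif a.score <= down_max:
            out.append(replace(a, category="down"))
        else:
            out.append(replace(a, category="balanced"))
    return out


def activities_to_frame(
    activities: Sequence[TadActivity],
    tads: Sequence[Tad] | None = None,
) -> pd.DataFrame:
    """Activity table, scored TADs first in descending score order
    (rank-plot layout), unscored last. Coordinates added when ``tads``
    is supplied."""
    coords = {}
    if tads is not None:
        coords = {
            t.tad_id: (t.interval.chrom, t.interval.start, t.interval.end)
            for t in tads
        }
    rows = []
    for a in activities:
        row: dict = {"tad_id": a.tad_id}
        if coords:
            chrom, start, end = coords[a.tad_id]
            row.update(chrom=chrom, start=start, end=end)
        row.update(
            n_gain=a.n_gain,
            n_loss=a.n_loss,
            score=a.score,
            category=a.category,
        )
        rows.append(row)
    df = pd.DataFrame.from_records(rows)
    return df.sort_values(
        "score", ascending=False, na_position="last", kind="mergesort"
    ).reset_index(drop=True)
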