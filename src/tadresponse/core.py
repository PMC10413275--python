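"""Genomic data model and coordinate arithmetic.

All coordinates are 0-based, half-open ``[start, end)`` (BED convention).
Inputs in 1-based conventions (GTF) are converted at read time so that no
other module ever sees a 1-based coordinate.

The record types here are deliberately small frozen dataclasses: they carry
exactly the attributes the downstream analysis consumes (an occupancy fold
change and its FDR for a differential region, a TSS and strand for a gene)
and validate their invariants on construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "CHROMATIN_STATES",
    "UNCOVERED",
    "ValidationError",
    "GenomicInterval",
    "DifferentialRegion",
    "Tad",
    "Gene",
    "ChromatinStateSegment",
    "Interaction",
    "overlap_bp",
    "validate_tads",
    "state_overlap_profile",
]

#: The 18 ChromHMM state labels (ENCODE 18-state model), promoter to quiescent.
CHROMATIN_STATES = (
    "TssA",
    "TssFlnk",
    "TssFlnkU",
    "TssFlnkD",
    "Tx",
    "TxWk",
    "EnhG1",
    "EnhG2",
    "EnhA1",
    "EnhA2",
    "EnhWk",
    "ZNF/Rpts",
    "Het",
    "TssBiv",
    "EnhBiv",
    "ReprPC",
    "ReprPCWk",
    "Quies",
)

#: Key under which nucleotides covered by no state segment are reported.
UNCOVERED = "uncovered"


class ValidationError(ValueError):
    """A record violated one of its declared invariants."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval ``[start, end)`` on a named chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("interval chromosome name must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        """Floor midpoint, used for unambiguous region-to-TAD assignment."""
        return (self.start + self.end) // 2

    def overlap(self, other: "GenomicInterval") -> int:
        return overlap_bp(self, other)

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end


def overlap_bp(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of nucleotides shared by two half-open intervals.

    Zero when the chromosomes differ or the intervals merely abut.
    """
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


@dataclass(frozen=True)
class DifferentialRegion:
    """A cis-regulatory interval with a significant occupancy change.

    ``occ_log2fc`` is the log2 fold change of coregulator (MED1/BRD4)
    occupancy after stimulation versus control; its sign defines the
    gain/loss direction, so a value of exactly zero is rejected.
    """

    region_id: str
    interval: GenomicInterval
    occ_log2fc: float
    occ_fdr: float

    def __post_init__(self) -> None:
        if self.occ_log2fc == 0:
            raise ValidationError(
                f"region {self.region_id}: occ_log2fc must be non-zero "
                "(direction is derived from its sign)"
            )
        if not (0.0 <= self.occ_fdr <= 1.0):
            raise ValidationError(
                f"region {self.region_id}: occ_fdr {self.occ_fdr} outside [0, 1]"
            )

    @property
    def direction(self) -> str:
        """``"gain"`` if occupancy increased, else ``"loss"``."""
        return "gain" if self.occ_log2fc > 0 else "loss"


@dataclass(frozen=True)
class Tad:
    """A topologically associating domain, consumed as a fixed interval."""

    tad_id: str
    interval: GenomicInterval


@dataclass(frozen=True)
class Gene:
    gene_id: str
    chrom: str
    tss: int
    strand: str

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise ValidationError(f"gene {self.gene_id}: negative TSS")
        if self.strand not in ("+", "-"):
            raise ValidationError(
                f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}"
            )


@dataclass(frozen=True)
class ChromatinStateSegment:
    interval: GenomicInterval
    state: str

    def __post_init__(self) -> None:
        if self.state not in CHROMATIN_STATES:
            raise ValidationError(
                f"unknown chromatin state {self.state!r}; "
                f"expected one of the 18-state model labels"
            )


@dataclass(frozen=True)
class Interaction:
    """A significant chromatin interaction between two anchor intervals."""

    anchor1: GenomicInterval
    anchor2: GenomicInterval
    significance: float | None = None

    def __post_init__(self) -> None:
        if self.significance is not None and not (0.0 <= self.significance <= 1.0):
            raise ValidationError(
                f"interaction significance {self.significance} outside [0, 1]"
            )


def validate_tads(tads: Sequence[Tad]) -> None:
    """Check that TADs on each chromosome are pairwise non-overlapping.

    Raises :class:`ValidationError` naming the first offending pair.
    """
    by_chrom: dict[str, list[Tad]] = {}
    for t in tads:
        by_chrom.setdefault(t.interval.chrom, []).append(t)
    for chrom, group in by_chrom.items():
        group = sorted(group, key=lambda t: (t.interval.start, t.interval.end))
        for prev, cur in zip(group, group[1:]):
            if cur.interval.start < prev.interval.end:
                raise ValidationError(
                    f"overlapping TADs on {chrom}: "
                    f"{prev.tad_id} [{prev.interval.start}, {prev.interval.end}) and "
                    f"{cur.tad_id} [{cur.interval.start}, {cur.interval.end})"
                )


def state_overlap_profile(
    regions: Sequence[GenomicInterval],
    segments: Sequence[ChromatinStateSegment],
) -> dict[str, float]:
    """Fraction of region nucleotides falling in each chromatin state.

    Fractions are taken over the total nucleotide content of ``regions``
    (regions contribute independently; overlapping regions count their
    shared bases once per region). Bases covered by no segment are reported
    under the :data:`UNCOVERED` key. The returned fractions sum to 1.

    Segments are assumed non-overlapping within a chromosome, as emitted by
    a ChromHMM-style segmentation.
    """
    if not regions:
        raise ValueError("state_overlap_profile: empty region list")

    seg_by_chrom: dict[str, list[ChromatinStateSegment]] = {}
    for seg in segments:
        seg_by_chrom.setdefault(seg.interval.chrom, []).append(seg)
    for group in seg_by_chrom.values():
        group.sort(key=lambda s: s.interval.start)

    total = sum(r.length for r in regions)
    bp: dict[str, int] = {}
    covered_total = 0
    for region in regions:
        for seg in seg_by_chrom.get(region.chrom, ()):
            ov = overlap_bp(region, seg.interval)
            if ov:
                bp[seg.state] = bp.get(seg.state, 0) + ov
                covered_total += ov
    profile = {state: n / total for state, n in sorted(bp.items())}
    uncovered = total - covered_total
    if uncovered:
        profile[UNCOVERED] = uncovered / total
    return profile
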