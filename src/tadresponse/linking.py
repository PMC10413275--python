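"""Gene regulatory domains and region-to-gene association.

Implements the "basal plus extension" regulatory-domain rule: every gene
gets a strand-aware basal window around its TSS (5 kb upstream / 1 kb
downstream by default); each basal edge then extends outward until it meets
the nearest neighbouring gene's basal-domain edge, capped at
``max_extension`` beyond the basal edge. A neighbouring basal domain that
already overlaps the gene's own basal domain never shrinks it below the
basal window.

Differential regions are linked to genes either *linearly* (>= 1 bp overlap
with a regulatory domain) or through a *3D interaction* (one anchor of a
significant chromatin interaction overlaps the region, the other overlaps a
promoter window of +/- ``promoter_halfwidth`` around the TSS).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree
from scipy import stats

from .core import DifferentialRegion, Gene, GenomicInterval, Interaction, overlap_bp

__all__ = [
    "LinkConfig",
    "RegulatoryDomain",
    "RegionGeneLink",
    "basal_domain",
    "build_regulatory_domains",
    "link_regions_to_genes",
    "links_per_gene",
    "signal_expression_correlation",
]


@dataclass(frozen=True)
class LinkConfig:
    """Geometry of the basal-plus-extension rule and interaction anchoring.

    Basal sizes are the canonical 5 kb upstream / 1 kb downstream of the
    TSS; the extension cap is 10 kb beyond each basal edge. The promoter
    half-width for interaction anchoring is +/- 2.5 kb around the TSS.
    """

    basal_up: int = 5_000
    basal_down: int = 1_000
    max_extension: int = 10_000
    promoter_halfwidth: int = 2_500

    def __post_init__(self) -> None:
        if min(self.basal_up, self.basal_down, self.max_extension, self.promoter_halfwidth) < 0:
            raise ValueError("LinkConfig distances must all be >= 0")
        if self.basal_up + self.basal_down == 0:
            raise ValueError("basal domain must have positive width")


@dataclass(frozen=True)
class RegulatoryDomain:
    gene_id: str
    interval: GenomicInterval


@dataclass(frozen=True)
class RegionGeneLink:
    region_id: str
    gene_id: str
    evidence: str  # "linear" | "interaction"

    def __post_init__(self) -> None:
        if self.evidence not in ("linear", "interaction"):
            raise ValueError(f"unknown evidence {self.evidence!r}")


def basal_domain(gene: Gene, cfg: LinkConfig) -> tuple[int, int]:
    """Unclipped basal window ``(start, end)``; strand-aware, may be negative."""
    if gene.strand == "+":
        return gene.tss - cfg.basal_up, gene.tss + cfg.basal_down
    return gene.tss - cfg.basal_down, gene.tss + cfg.basal_up


def build_regulatory_domains(
    genes: Sequence[Gene],
    chrom_sizes: Mapping[str, int],
    cfg: LinkConfig = LinkConfig(),
) -> list[RegulatoryDomain]:
    """Basal-plus-extension regulatory domains, one per gene.

    Each edge extends outward from the basal edge to the nearest basal-domain
    edge of a flanking gene (genes with strictly smaller TSS obstruct the
    left edge, strictly larger the right; a co-located TSS obstructs both),
    capped at ``max_extension``, never shrinking below the basal window, and
    clipped to ``[0, chromosome length)``.
    """
    for g in genes:
        if g.chrom not in chrom_sizes:
            raise ValueError(f"gene {g.gene_id}: unknown chromosome {g.chrom}")
        if g.tss >= chrom_sizes[g.chrom]:
            raise ValueError(
                f"gene {g.gene_id}: TSS {g.tss} outside chromosome "
                f"{g.chrom} (length {chrom_sizes[g.chrom]})"
            )

    by_chrom: dict[str, list[Gene]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)

    domains: dict[str, RegulatoryDomain] = {}
    for chrom, group in by_chrom.items():
        clen = chrom_sizes[chrom]
        order = sorted(range(len(group)), key=lambda i: (group[i].tss, group[i].gene_id))
        basal = [basal_domain(group[i], cfg) for i in order]
        tss = [group[i].tss for i in order]

        # prefix max of basal ends over genes with smaller TSS, and suffix
        # min of basal starts over genes with larger TSS: the nearest
        # obstruction can come from any flanking gene, not just the adjacent
        # one, when basal windows are strand-asymmetric.
        n = len(order)
        left_obstruction = [None] * n   # max basal end among j with tss_j < tss_i
        right_obstruction = [None] * n  # min basal start among j with tss_j > tss_i
        running = None
        for i in range(n):
            j = i - 1
            # include ties (equal TSS) as obstructions on both sides
            left_obstruction[i] = running
            if i > 0 and tss[i - 1] == tss[i]:
                left_obstruction[i] = (
                    basal[i - 1][1] if running is None else max(running, basal[i - 1][1])
                )
            running = basal[i][1] if running is None else max(running, basal[i][1])
        running = None
        for i in range(n - 1, -1, -1):
            right_obstruction[i] = running
            if i < n - 1 and tss[i + 1] == tss[i]:
                right_obstruction[i] = (
                    basal[i + 1][0] if running is None else min(running, basal[i + 1][0])
                )
            running = basal[i][0] if running is None else min(running, basal[i][0])

        for rank, i in enumerate(order):
            b_start, b_end = basal[rank]
            left = b_start - cfg.max_extension
            if left_obstruction[rank] is not None:
                left = max(left, left_obstruction[rank])
            right = b_end + cfg.max_extension
            if right_obstruction[rank] is not None:
                right = min(right, right_obstruction[rank])
            # never shrink below the basal window, then clip to the chromosome
            start = max(0, min(left, b_start))
            end = min(clen, max(right, b_end))
            gene = group[i]
            domains[gene.gene_id] = RegulatoryDomain(
                gene.gene_id, GenomicInterval(chrom, start, end)
            )
    # preserve input gene order
    return [domains[g.gene_id] for g in genes]


def link_regions_to_genes(
    regions: Sequence[DifferentialRegion],
    domains: Sequence[RegulatoryDomain],
    interactions: Sequence[Interaction],
    genes: Sequence[Gene],
    cfg: LinkConfig = LinkConfig(),
) -> list[RegionGeneLink]:
    """Union of linear and interaction-mediated region-gene links.

    Returns one :class:`RegionGeneLink` per distinct (region, gene,
    evidence) triple, sorted for order-invariance. With ``interactions``
    empty the result is exactly the linear assignment.
    """
    links: set[tuple[str, str, str]] = set()

    domain_trees: dict[str, IntervalTree] = {}
    for d in domains:
        tree = domain_trees.setdefault(d.interval.chrom, IntervalTree())
        tree.addi(d.interval.start, d.interval.end, d.gene_id)
    for region in regions:
        tree = domain_trees.get(region.interval.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(region.interval.start, region.interval.end):
            links.add((region.region_id, hit.data, "linear"))

    if interactions:
        promoter_trees: dict[str, IntervalTree] = {}
        for g in genes:
            start = max(0, g.tss - cfg.promoter_halfwidth)
            end = g.tss + cfg.promoter_halfwidth
            if end > start:
                tree = promoter_trees.setdefault(g.chrom, IntervalTree())
                tree.addi(start, end, g.gene_id)
        region_trees: dict[str, IntervalTree] = {}
        for r in regions:
            tree = region_trees.setdefault(r.interval.chrom, IntervalTree())
            tree.addi(r.interval.start, r.interval.end, r.region_id)

        def _hits(trees, iv: GenomicInterval):
            tree = trees.get(iv.chrom)
            return [] if tree is None else [h.data for h in tree.overlap(iv.start, iv.end)]

        for ia in interactions:
            for reg_anchor, prom_anchor in ((ia.anchor1, ia.anchor2), (ia.anchor2, ia.anchor1)):
                region_ids = _hits(region_trees, reg_anchor)
                if not region_ids:
                    continue
                for gene_id in _hits(promoter_trees, prom_anchor):
                    for region_id in region_ids:
                        links.add((region_id, gene_id, "interaction"))

    return [RegionGeneLink(*triple) for triple in sorted(links)]


def links_per_gene(links: Sequence[RegionGeneLink]) -> dict[str, dict]:
    """Distinct-region count per gene with the 1 / 2+ multiplicity stratum.

    A gene linked to the same region by both evidence types counts that
    region once. Genes with no links are simply absent (stratum "0" exists
    only for callers that ask about unlinked genes explicitly).
    """
    regions_by_gene: dict[str, set[str]] = {}
    for link in links:
        regions_by_gene.setdefault(link.gene_id, set()).add(link.region_id)
    return {
        gene_id: {"n_regions": len(regs), "stratum": "1" if len(regs) == 1 else "2+"}
        for gene_id, regs in regions_by_gene.items()
    }


def signal_expression_correlation(
    pairs: Sequence[tuple[float, float]],
) -> tuple[float, float, int]:
    """Pearson correlation between a region signal and gene log2FC.

    Returns ``(r, two-sided p, n)``. The region-signal coordinate is
    whatever the caller supplies (e.g. log2 read density at the region or
    its change); callers should record that choice alongside the result.
    """
    n = len(pairs)
    if n < 3:
        raise ValueError(f"signal_expression_correlation: need n >= 3, got {n}")
    x = np.asarray([p[0] for p in pairs], dtype=float)
    y = np.asarray([p[1] for p in pairs], dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError(
            "signal_expression_correlation: constant coordinate, correlation undefined"
        )
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), n
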