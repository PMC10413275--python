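"""Statsmodels-style front end: a model built from the input tables whose
``fit()`` runs the whole regionalized-response analysis and returns a
results object with the estimates, tests and summary table.

The analysis chain: classify gene responses from the expression time
course; build basal-plus-extension regulatory domains and link differential
regions to genes (linearly and through chromatin interactions); assign
regions to TADs, score each TAD as gain/(gain+loss) and classify it
up/balanced/down; test the score distribution for bimodality (dip test);
assign genes to TADs and run the enrichment battery (permutation test of
regulated genes in responsive TADs, Fisher and chi-squared association of
gene direction with TAD category, Pearson-residual flags); compare
time-course amplitudes of linked versus unlinked genes.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import DifferentialRegion, Gene, Interaction, Tad
from . import io as tio
from .expression import (
    GeneCallConfig,
    GeneResponse,
    cohort_summary,
    classify_table,
    responses_to_frame,
)
from .linking import (
    LinkConfig,
    RegionGeneLink,
    build_regulatory_domains,
    link_regions_to_genes,
    links_per_gene,
    signal_expression_correlation,
)
from .tads import (
    UNASSIGNED,
    DipResult,
    activities_to_frame,
    assign_genes_to_tads,
    assign_regions_to_tads,
    classify_tads,
    dip_test,
    score_tads,
)
from .enrichment import (
    ContingencyTable,
    chisq_with_residuals,
    fisher_2x2,
    permutation_gene_tad_enrichment,
    timecourse_comparison,
)

__all__ = ["TadResponseModel", "TadResponseResults", "stage_seed"]


def stage_seed(seed: int, stage: str) -> int:
    """Fork a global seed per stage by stable name hashing, so adding a
    stage never perturbs the draws of earlier stages."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


class TadResponseModel:
    """Joint model of coregulator redistribution and gene response.

    Parameters
    ----------
    regions, tads, genes, interactions
        Typed records (see :mod:`tadresponse.core`); interactions optional.
    expression
        Long-format DE table (gene_id, timepoint, log2fc, padj).
    counts
        Optional gene x sample count matrix for the activity filter.
    chrom_sizes
        Chromosome lengths; inferred from the TAD extents when omitted.
    """

    def __init__(
        self,
        regions: Sequence[DifferentialRegion],
        tads: Sequence[Tad],
        genes: Sequence[Gene],
        expression: pd.DataFrame,
        interactions: Sequence[Interaction] = (),
        counts: pd.DataFrame | None = None,
        chrom_sizes: Mapping[str, int] | None = None,
        gene_config: GeneCallConfig = GeneCallConfig(),
        link_config: LinkConfig = LinkConfig(),
        up_min: float = 0.7,
        down_max: float = 0.3,
    ):
        self.regions = list(regions)
        self.tads = list(tads)
        self.genes = list(genes)
        self.interactions = list(interactions)
        self.expression = expression
        self.counts = counts
        self.gene_config = gene_config
        self.link_config = link_config
        self.up_min = up_min
        self.down_max = down_max
        if chrom_sizes is None:
            chrom_sizes = {}
            for t in self.tads:
                c = t.interval.chrom
                chrom_sizes[c] = max(chrom_sizes.get(c, 0), t.interval.end)
            for g in self.genes:
                chrom_sizes[g.chrom] = max(chrom_sizes.get(g.chrom, 0), g.tss + 1)
        self.chrom_sizes = dict(chrom_sizes)

    @classmethod
    def from_files(
        cls,
        regions: str | Path,
        tads: str | Path,
        genes: str | Path,
        expression: str | Path,
        interactions: str | Path | None = None,
        counts: str | Path | None = None,
        **kwargs,
    ) -> "TadResponseModel":
        return cls(
            regions=tio.read_bed(regions, "region"),
            tads=tio.read_bed(tads, "tad"),
            genes=tio.read_genes(genes),
            expression=tio.read_expression(expression),
            interactions=tio.read_bedpe(interactions) if interactions else (),
            counts=tio.read_counts(counts) if counts else None,
            **kwargs,
        )

    @classmethod
    def from_simulation(cls, sim, **kwargs) -> "TadResponseModel":
        """Build directly from a :class:`~tadresponse.simulate.SimData`."""
        return cls(
            regions=sim.regions,
            tads=sim.tads,
            genes=sim.genes,
            expression=sim.expression,
            interactions=sim.interactions,
            counts=sim.counts,
            chrom_sizes=sim.chrom_sizes,
            **kwargs,
        )

    # ------------------------------------------------------------------

    def fit(
        self,
        n_perm: int = 10_000,
        dip_null: int = 999,
        seed: int = 0,
    ) -> "TadResponseResults":
        """Run every stage; deterministic given ``seed``."""
        responses = classify_table(self.expression, self.counts, self.gene_config)
        domains = build_regulatory_domains(self.genes, self.chrom_sizes, self.link_config)
        links = link_regions_to_genes(
            self.regions, domains, self.interactions, self.genes, self.link_config
        )
        region_tad = assign_regions_to_tads(self.regions, self.tads)
        activities = classify_tads(
            score_tads(region_tad, self.regions, self.tads), self.up_min, self.down_max
        )
        gene_tad = assign_genes_to_tads(self.genes, self.tads)

        scores = [a.score for a in activities if a.score is not None]
        dip = None
        if len(scores) >= 4:
            dip = dip_test(scores, n_null=dip_null, seed=stage_seed(seed, "dip"))

        return TadResponseResults(
            model=self,
            seed=seed,
            n_perm=n_perm,
            responses=responses,
            domains=domains,
            links=links,
            region_tad=region_tad,
            gene_tad=gene_tad,
            activities=activities,
            dip=dip,
        )


@dataclass
class TadResponseResults:
    """Fitted quantities, tests and summaries of a :class:`TadResponseModel`."""

    model: TadResponseModel
    seed: int
    n_perm: int
    responses: list[GeneResponse]
    domains: list
    links: list[RegionGeneLink]
    region_tad: dict[str, str]
    gene_tad: dict[str, str]
    activities: list
    dip: DipResult | None

    def __post_init__(self) -> None:
        self._compute_tests()

    # -- derived sets ---------------------------------------------------

    @property
    def call_of(self) -> dict[str, str]:
        return {r.gene_id: r.call for r in self.responses}

    @property
    def category_of(self) -> dict[str, str]:
        return {a.tad_id: a.category for a in self.activities}

    @property
    def responsive_tads(self) -> set[str]:
        return {a.tad_id for a in self.activities if a.category in ("up", "down")}

    @property
    def linked_genes(self) -> set[str]:
        return {l.gene_id for l in self.links}

    def _universe(self) -> list[str]:
        """Non-inactive genes assigned to a TAD: the enrichment background."""
        return [
            r.gene_id
            for r in self.responses
            if r.call != "inactive" and self.gene_tad.get(r.gene_id, UNASSIGNED) != UNASSIGNED
        ]

    # -- statistics -----------------------------------------------------

    def _compute_tests(self) -> None:
        category_of = self.category_of
        call_of = self.call_of
        universe = self._universe()
        regulated = [g for g in universe if call_of[g] in ("activated", "repressed")]
        responsive = self.responsive_tads

        self.cohort = cohort_summary(self.responses)

        # permutation test of regulated genes within responsive TADs
        self.permutation = None
        if regulated and universe and responsive:
            self.permutation = permutation_gene_tad_enrichment(
                regulated,
                universe,
                self.gene_tad,
                responsive,
                n_perm=self.n_perm,
                seed=stage_seed(self.seed, "permutation"),
            )

        # Fisher: activated x up-TAD and repressed x down-TAD
        self.fisher = {}
        for call, cat in (("activated", "up"), ("repressed", "down")):
            a = b = c = d = 0
            for g in universe:
                in_call = call_of[g] == call
                in_cat = category_of.get(self.gene_tad[g]) == cat
                if in_call and in_cat:
                    a += 1
                elif in_call:
                    b += 1
                elif in_cat:
                    c += 1
                else:
                    d += 1
            if min(a + b, c + d) > 0 and min(a + c, b + d) > 0:
                self.fisher[f"{call}_x_{cat}"] = fisher_2x2(
                    ContingencyTable(
                        (call, f"not_{call}"),
                        (f"{cat}_tad", f"not_{cat}_tad"),
                        ((a, b), (c, d)),
                    )
                )

        # chi-squared: gene direction x TAD category, for regulated genes in
        # scored TADs, overall and stratified by direct linkage
        linked = self.linked_genes
        self.chisq = {}
        for name, keep in (
            ("all", lambda g: True),
            ("linked", lambda g: g in linked),
            ("unlinked", lambda g: g not in linked),
        ):
            tab = self._direction_category_table([g for g in regulated if keep(g)])
            if tab is not None:
                try:
                    self.chisq[name] = chisq_with_residuals(tab)
                except ValueError:
                    pass

        # time-course comparisons
        self.timecourse_linked = self._timecourse_linked(regulated, responsive)
        self.timecourse_multiplicity = self._timecourse_multiplicity(regulated)

        # region signal vs expression correlation at the earliest timepoint
        self.correlation = self._signal_correlation()

        self.summary_dict = self._summary_dict()

    def _direction_category_table(self, genes: list[str]) -> ContingencyTable | None:
        cats = ("up", "balanced", "down")
        counts = {call: {c: 0 for c in cats} for call in ("activated", "repressed")}
        call_of, category_of = self.call_of, self.category_of
        n = 0
        for g in genes:
            cat = category_of.get(self.gene_tad[g])
            call = call_of[g]
            if cat in cats and call in counts:
                counts[call][cat] += 1
                n += 1
        if n == 0:
            return None
        rows = tuple(counts)
        # drop all-zero columns to keep margins positive
        keep = tuple(c for c in cats if any(counts[r][c] for r in rows))
        if len(keep) < 2:
            return None
        return ContingencyTable(
            rows, keep, tuple(tuple(counts[r][c] for c in keep) for r in rows)
        )

    def _trajectories(self, genes: set[str]) -> pd.DataFrame:
        rows = {
            r.gene_id: {t: v for t, v in r.trajectory}
            for r in self.responses
            if r.gene_id in genes
        }
        return pd.DataFrame.from_dict(rows, orient="index")

    def _timepoints(self) -> list[float]:
        return sorted({t for r in self.responses for t, _ in r.trajectory})

    def _timecourse_linked(self, regulated, responsive) -> pd.DataFrame | None:
        """Amplitude (|log2FC|) of linked vs unlinked regulated genes in
        responsive TADs, Mann-Whitney per timepoint with BH correction."""
        in_resp = [g for g in regulated if self.gene_tad[g] in responsive]
        linked = {g for g in in_resp if g in self.linked_genes}
        unlinked = set(in_resp) - linked
        if not linked or not unlinked:
            return None
        fa = self._trajectories(linked).abs()
        fb = self._trajectories(unlinked).abs()
        return timecourse_comparison(fa, fb, self._timepoints())

    def _timecourse_multiplicity(self, regulated) -> pd.DataFrame | None:
        """Amplitude of regulated genes linked to one vs 2+ regions."""
        per_gene = links_per_gene(self.links)
        one = {g for g in regulated if per_gene.get(g, {}).get("stratum") == "1"}
        multi = {g for g in regulated if per_gene.get(g, {}).get("stratum") == "2+"}
        if not one or not multi:
            return None
        return timecourse_comparison(
            self._trajectories(multi).abs(),
            self._trajectories(one).abs(),
            self._timepoints(),
        )

    def _signal_correlation(self):
        tps = self._timepoints()
        if not tps:
            return None
        t0 = 1.0 if 1.0 in tps else tps[0]
        lfc_at = {
            r.gene_id: r.log2fc_at(t0)
            for r in self.responses
            if r.call in ("activated", "repressed")
        }
        occ = {r.region_id: r.occ_log2fc for r in self.model.regions}
        pairs = [
            (occ[l.region_id], lfc_at[l.gene_id])
            for l in self.links
            if l.gene_id in lfc_at and lfc_at[l.gene_id] is not None
        ]
        if len(pairs) < 3:
            return None
        try:
            r, p, n = signal_expression_correlation(pairs)
        except ValueError:
            return None
        return {"pearson_r": r, "p_value": p, "n": n, "timepoint": t0,
                "region_value": "occ_log2fc"}

    # -- reporting ------------------------------------------------------

    def _summary_dict(self) -> dict:
        acts = self.activities
        n_tads = len(acts)
        n_scored = sum(a.score is not None for a in acts)
        cat_counts = {c: sum(a.category == c for a in acts) for c in ("up", "balanced", "down")}
        universe = self._universe()
        call_of = self.call_of
        regulated = [g for g in universe if call_of[g] in ("activated", "repressed")]
        responsive = self.responsive_tads
        reg_in_resp = [g for g in regulated if self.gene_tad[g] in responsive]
        linked_in_resp = [g for g in reg_in_resp if g in self.linked_genes]

        out = {
            "seed": self.seed,
            "n_genes": len(self.responses),
            "cohort": dict(self.cohort),
            "n_tads": n_tads,
            "n_scored_tads": n_scored,
            "pct_tads_scored": 100.0 * n_scored / n_tads if n_tads else math.nan,
            "tad_categories": cat_counts,
            "n_regions": len(self.model.regions),
            "n_links": len(self.links),
            "n_regulated_in_responsive": len(reg_in_resp),
            "pct_regulated_in_responsive": (
                100.0 * len(reg_in_resp) / len(regulated) if regulated else math.nan
            ),
            "pct_responsive_genes_linked": (
                100.0 * len(linked_in_resp) / len(reg_in_resp) if reg_in_resp else math.nan
            ),
        }
        if self.dip is not None:
            out["dip"] = {"dip": self.dip.dip, "p_value": self.dip.p_value, "n": self.dip.n}
        if self.permutation is not None:
            out["permutation"] = {
                "observed": self.permutation.observed,
                "n_perm": self.permutation.n_perm,
                "p_value": self.permutation.p_value,
            }
        out["fisher"] = {
            k: {kk: (None if kk == "odds_ratio" and math.isinf(vv) else vv) for kk, vv in v.items()}
            for k, v in self.fisher.items()
        }
        out["chisq"] = {
            k: {"chi2": v.chi2, "df": v.df, "p_value": v.p_value} for k, v in self.chisq.items()
        }
        if self.correlation is not None:
            out["correlation"] = self.correlation
        return out

    def audit(self) -> None:
        """Recompute the summary percentages from the emitted tables and
        fail loudly on any inconsistency."""
        s = self.summary_dict
        frame = self.tad_activity_frame()
        n_scored = int(frame["score"].notna().sum())
        assert n_scored == s["n_scored_tads"], "scored-TAD count mismatch"
        cohort = responses_to_frame(self.responses)["call"].value_counts().to_dict()
        for call in ("activated", "repressed", "inactive"):
            assert cohort.get(call, 0) == s["cohort"][call], f"{call} count mismatch"
        if s["n_tads"]:
            pct = 100.0 * n_scored / s["n_tads"]
            assert abs(pct - s["pct_tads_scored"]) < 1e-9, "pct_tads_scored mismatch"

    def gene_response_frame(self) -> pd.DataFrame:
        df = responses_to_frame(self.responses)
        df["tad_id"] = df["gene_id"].map(self.gene_tad)
        df["tad_category"] = df["tad_id"].map(self.category_of).fillna(UNASSIGNED)
        per_gene = links_per_gene(self.links)
        df["n_linked_regions"] = df["gene_id"].map(
            lambda g: per_gene.get(g, {}).get("n_regions", 0)
        )
        return df

    def tad_activity_frame(self) -> pd.DataFrame:
        return activities_to_frame(self.activities, self.model.tads)

    def links_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(l.region_id, l.gene_id, l.evidence) for l in self.links],
            columns=["region_id", "gene_id", "evidence"],
        )

    def summary(self) -> str:
        """Human-readable run summary."""
        s = self.summary_dict
        lines = [
            "TAD regionalized-response analysis",
            "=" * 50,
            f"genes: {s['n_genes']}  (activated {s['cohort']['activated']}, "
            f"repressed {s['cohort']['repressed']}, unchanged {s['cohort']['unchanged']}, "
            f"inactive {s['cohort']['inactive']})",
            f"regions: {s['n_regions']}  region-gene links: {s['n_links']}",
            f"TADs: {s['n_tads']}  scored: {s['n_scored_tads']} "
            f"({s['pct_tads_scored']:.1f}%)",
            f"TAD categories: up {s['tad_categories']['up']}, "
            f"balanced {s['tad_categories']['balanced']}, "
            f"down {s['tad_categories']['down']}",
        ]
        if "dip" in s:
            lines.append(
                f"dip test of score bimodality: dip {s['dip']['dip']:.4f}, "
                f"p = {s['dip']['p_value']:.3g} (n = {s['dip']['n']})"
            )
        lines.append(
            f"regulated genes in responsive TADs: {s['n_regulated_in_responsive']} "
            f"({s['pct_regulated_in_responsive']:.1f}%)"
        )
        lines.append(
            f"  of which linked to a differential region: "
            f"{s['pct_responsive_genes_linked']:.1f}%"
        )
        if "permutation" in s:
            p = s["permutation"]
            lines.append(
                f"permutation enrichment: observed {p['observed']}, "
                f"n_perm {p['n_perm']}, p = {p['p_value']:.3g}"
            )
        for k, v in s["fisher"].items():
            orr = v["odds_ratio"]
            orr = "inf" if orr is None else f"{orr:.2f}"
            lines.append(f"Fisher {k}: OR = {orr}, p = {v['p_value']:.3g}")
        for k, v in s["chisq"].items():
            lines.append(
                f"chi-squared ({k}): chi2 = {v['chi2']:.2f}, df = {v['df']}, "
                f"p = {v['p_value']:.3g}"
            )
        if "correlation" in s:
            c = s["correlation"]
            lines.append(
                f"occupancy-expression correlation (t = {c['timepoint']:g} h): "
                f"r = {c['pearson_r']:.3f}, p = {c['p_value']:.3g}, n = {c['n']}"
            )
        return "\n".join(lines)

    def save(self, outdir: str | Path) -> None:
        """Write every intermediate table plus summary.json."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.gene_response_frame().to_csv(outdir / "gene_responses.tsv", sep="\t", index=False)
        self.tad_activity_frame().to_csv(outdir / "tad_activity.tsv", sep="\t", index=False)
        self.links_frame().to_csv(outdir / "links.tsv", sep="\t", index=False)
        for name, df in (
            ("timecourse_linked_vs_unlinked", self.timecourse_linked),
            ("timecourse_1_vs_2plus", self.timecourse_multiplicity),
        ):
            if df is not None:
                df.to_csv(outdir / f"{name}.tsv", sep="\t", index=False)
        for name, res in self.chisq.items():
            res.to_long_frame().to_csv(
                outdir / f"association_{name}.tsv", sep="\t", index=False
            )
        if self.dip is not None:
            with open(outdir / "dip.json", "w") as fh:
                json.dump(
                    {
                        "dip": self.dip.dip,
                        "p_value": self.dip.p_value,
                        "n": self.dip.n,
                        "n_null": self.dip.n_null,
                        "seed": self.dip.seed,
                    },
                    fh,
                    indent=2,
                )
                fh.write("\n")
        with open(outdir / "summary.json", "w") as fh:
            json.dump(self.summary_dict, fh, indent=2, sort_keys=True, default=float)
            fh.write("\n")

    # -- plotting (optional matplotlib) ---------------------------------

    def plot_score_distribution(self, ax=None):
        """Histogram of TAD scores with category thresholds."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        scores = [a.score for a in self.activities if a.score is not None]
        ax.hist(scores, bins=20, color="0.6", edgecolor="white")
        ax.axvline(self.model.up_min, color="firebrick", ls="--", lw=1)
        ax.axvline(self.model.down_max, color="seagreen", ls="--", lw=1)
        ax.set_xlabel("TAD score  gain / (gain + loss)")
        ax.set_ylabel("TADs")
        return ax

    def plot_trajectories(self, ax=None):
        """Mean +/- SEM amplitude of linked vs unlinked regulated genes."""
        import matplotlib.pyplot as plt

        from .expression import trajectory_summary

        if ax is None:
            _, ax = plt.subplots()
        regulated = [
            r for r in self.responses if r.call in ("activated", "repressed")
        ]
        responsive = self.responsive_tads
        groups = {
            "linked": [
                r
                for r in regulated
                if r.gene_id in self.linked_genes
                and self.gene_tad.get(r.gene_id) in responsive
            ],
            "unlinked": [
                r
                for r in regulated
                if r.gene_id not in self.linked_genes
                and self.gene_tad.get(r.gene_id) in responsive
            ],
        }
        tps = self._timepoints()
        for label, group in groups.items():
            if not group:
                continue
            absd = [
                GeneResponse(g.gene_id, g.call, tuple((t, abs(v)) for t, v in g.trajectory))
                for g in group
            ]
            df = trajectory_summary(absd, tps)
            ax.errorbar(
                df["timepoint"], df["mean_log2fc"], yerr=df["sem"], label=label, capsize=2
            )
        ax.set_xlabel("time after stimulation (h)")
        ax.set_ylabel("|log2 fold change|")
        ax.legend()
        return ax
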