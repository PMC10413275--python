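"""Seed-deterministic synthetic datasets with the regionalized-response
structure the analysis assumes, plus the latent truth for recovery tests.

The generator emulates the study's inputs at desk scale: chromosomes tiled
by non-overlapping TADs (log-normal sizes); each TAD carries a latent class
(up / down / neutral); responsive TADs receive differential regions whose
gain/loss direction is class-conditional, which makes the TAD-score
distribution bimodal; genes live inside TADs, a fraction of those in
responsive TADs are directly linked to a region (linearly through their
regulatory domain or through a chromatin interaction to their promoter),
and gene log2 fold-change trajectories follow a saturating ramp whose
amplitude is larger for linked genes than for unlinked genes in responsive
TADs and zero in neutral TADs, plus Gaussian noise.

Adjusted p-values are a deterministic monotone transform of
``|log2fc| / noise_sd`` (two-sided normal tail) — enough to exercise the
classifier thresholds without fitting a differential-expression model.

Defaults mirror the study conditions: ~37% of TADs responsive with the
up:down imbalance of the reported 75%/16% split, an average of 3.4 regions
per responsive TAD, gain probability 0.9 in up TADs and 0.1 in down TADs,
~40% of responsive-TAD genes directly linked, and a linked amplitude
(2.0) clearly above the environment amplitude (0.6).
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import erfc

from .core import DifferentialRegion, Gene, GenomicInterval, Interaction, Tad
from . import io as tio
from .expression import GeneResponse
from .tads import TadActivity

__all__ = ["SimConfig", "SimTruth", "SimData", "simulate", "truth_vs_inferred"]


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    n_chrom: int = 5
    chrom_length: int = 40_000_000
    tad_size_mean: float = 800_000.0  # mean TAD size in bp (log-normal)
    tad_size_sd: float = 400_000.0
    p_up: float = 0.28  # latent class probabilities; remainder is neutral
    p_down: float = 0.09
    regions_per_responsive_tad: float = 3.4  # Poisson mean, minimum 1
    p_gain_given_up: float = 0.9
    p_gain_given_down: float = 0.1
    genes_per_tad_mean: float = 4.0
    p_gene_linked: float = 0.4  # direct region linkage within responsive TADs
    effect_linked: float = 2.0  # log2FC plateau amplitude, linked genes
    effect_environment: float = 0.6  # unlinked genes in responsive TADs
    noise_sd: float = 0.3  # per-timepoint Gaussian noise on log2FC
    timepoints: tuple[float, ...] = (0.5, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0)
    interaction_fraction: float = 0.25  # linked genes wired in 3D, not linearly
    p_inactive: float = 0.1  # genes failing the read-count activity filter
    n_samples: int = 16  # columns of the emitted count matrix
    region_width: int = 1_000
    background_region_rate: float = 0.0  # Poisson mean of noise regions per neutral TAD
    ramp_tau: float = 1.2  # hours; trajectory ~ 1 - exp(-t / tau)

    def __post_init__(self) -> None:
        for name in (
            "p_up",
            "p_down",
            "p_gain_given_up",
            "p_gain_given_down",
            "p_gene_linked",
            "interaction_fraction",
            "p_inactive",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} = {v} outside [0, 1]")
        if self.p_up + self.p_down > 1.0:
            raise ValueError("p_up + p_down must be <= 1")
        if not (self.effect_linked > self.effect_environment >= 0.0):
            raise ValueError("require effect_linked > effect_environment >= 0")
        if self.tad_size_mean >= self.chrom_length:
            raise ValueError("infeasible geometry: mean TAD size exceeds chromosome length")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class SimTruth:
    """Latent structure: per-TAD class and per-gene assignment."""

    tad_classes: dict[str, str]  # tad_id -> up | down | neutral
    genes: pd.DataFrame  # gene_id, tad_id, linked, true_class, active


@dataclass(frozen=True)
class SimData:
    """Everything :func:`simulate` produced, in memory."""

    config: SimConfig
    chrom_sizes: dict[str, int]
    tads: list[Tad]
    regions: list[DifferentialRegion]
    genes: list[Gene]
    interactions: list[Interaction]
    expression: pd.DataFrame  # long format: gene_id, timepoint, log2fc, padj
    counts: pd.DataFrame  # gene_id x sample
    truth: SimTruth


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Convert a desired mean/sd of the size distribution to (mu, sigma)."""
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def _padj(abs_l2fc: np.ndarray, noise_sd: float) -> np.ndarray:
    """Deterministic monotone map |log2fc|/noise -> two-sided normal tail."""
    if noise_sd == 0.0:
        return np.where(abs_l2fc > 0, 0.0, 1.0)
    return np.minimum(1.0, erfc(abs_l2fc / noise_sd / math.sqrt(2.0)))


def simulate(cfg: SimConfig, outdir: str | Path | None = None) -> SimData:
    """Generate one dataset; write its files when ``outdir`` is given.

    Same config (including seed) gives byte-identical files. Emits exactly
    the formats the readers consume: TAD BED4, region BED6+2, gene TSV,
    interaction BEDPE, long expression TSV, count TSV, plus truth tables
    and a manifest JSON with the full config.
    """
    rng = np.random.default_rng(cfg.seed)
    mu, sigma = _lognormal_params(cfg.tad_size_mean, cfg.tad_size_sd)
    min_tad = max(50_000, cfg.region_width * 4)

    chrom_sizes = {f"chr{i + 1}": cfg.chrom_length for i in range(cfg.n_chrom)}
    tads: list[Tad] = []
    regions: list[DifferentialRegion] = []
    genes: list[Gene] = []
    interactions: list[Interaction] = []
    tad_classes: dict[str, str] = {}
    gene_rows: list[dict] = []
    expr_rows: list[dict] = []

    t_arr = np.asarray(cfg.timepoints, dtype=float)
    ramp = 1.0 - np.exp(-t_arr / cfg.ramp_tau)

    gene_counter = 0
    region_counter = 0
    for chrom in chrom_sizes:
        pos = 0
        tad_i = 0
        while pos < cfg.chrom_length - min_tad:
            size = int(rng.lognormal(mu, sigma))
            size = max(min_tad, min(size, cfg.chrom_length - pos))
            tad_id = f"{chrom}_tad{tad_i}"
            interval = GenomicInterval(chrom, pos, pos + size)
            tads.append(Tad(tad_id, interval))
            cls = rng.choice(
                ("up", "down", "neutral"),
                p=(cfg.p_up, cfg.p_down, 1.0 - cfg.p_up - cfg.p_down),
            )
            tad_classes[tad_id] = str(cls)
            pos += size
            tad_i += 1

    # genes, regions and trajectories per TAD (second pass keeps the TAD
    # geometry draw independent of downstream parameter choices)
    for tad in tads:
        tad_id = tad.tad_id
        cls = tad_classes[tad_id]
        iv = tad.interval
        responsive = cls in ("up", "down")
        p_gain = {
            "up": cfg.p_gain_given_up,
            "down": cfg.p_gain_given_down,
            "neutral": 0.5,
        }[cls]
        sign = {"up": 1.0, "down": -1.0, "neutral": 0.0}[cls]

        n_genes = int(rng.poisson(cfg.genes_per_tad_mean))
        tad_genes: list[tuple[Gene, bool, bool]] = []  # (gene, linked, active)
        for _ in range(n_genes):
            gene_id = f"g{gene_counter:05d}"
            gene_counter += 1
            tss = int(rng.integers(iv.start, iv.end))
            strand = "+" if rng.random() < 0.5 else "-"
            gene = Gene(gene_id, iv.chrom, tss, strand)
            genes.append(gene)
            active = rng.random() >= cfg.p_inactive
            linked = bool(
                active and responsive and rng.random() < cfg.p_gene_linked
            )
            tad_genes.append((gene, linked, active))

        # region placement
        def _place_region(center: int, lfc_sign: float) -> DifferentialRegion:
            nonlocal region_counter
            half = cfg.region_width // 2
            start = int(np.clip(center - half, iv.start, iv.end - cfg.region_width))
            region = DifferentialRegion(
                f"r{region_counter:05d}",
                GenomicInterval(iv.chrom, start, start + cfg.region_width),
                lfc_sign * (0.25 + abs(rng.normal(1.25, 0.5))),
                float(rng.uniform(1e-8, 0.049)),
            )
            region_counter += 1
            regions.append(region)
            return region

        def _direction_sign() -> float:
            return 1.0 if rng.random() < p_gain else -1.0

        n_linked_here = 0
        if responsive:
            n_regions = max(1, int(rng.poisson(cfg.regions_per_responsive_tad)))
            for gene, linked, _active in tad_genes:
                if not linked:
                    continue
                n_linked_here += 1
                region = _place_region(
                    int(rng.integers(iv.start, iv.end)), _direction_sign()
                ) if rng.random() < cfg.interaction_fraction else None
                if region is not None:
                    # 3D wiring: anchor over the region, anchor over the promoter
                    a1 = GenomicInterval(
                        iv.chrom,
                        max(0, region.interval.start - 1_000),
                        region.interval.end + 1_000,
                    )
                    a2 = GenomicInterval(
                        iv.chrom, max(0, gene.tss - 2_000), gene.tss + 2_000
                    )
                    interactions.append(
                        Interaction(a1, a2, float(rng.uniform(1e-6, 0.01)))
                    )
                else:
                    # linear wiring: region on top of the TSS, inside the
                    # basal domain hence inside the regulatory domain
                    _place_region(gene.tss, _direction_sign())
            for _ in range(max(0, n_regions - n_linked_here)):
                _place_region(int(rng.integers(iv.start, iv.end)), _direction_sign())
        elif cfg.background_region_rate > 0:
            for _ in range(int(rng.poisson(cfg.background_region_rate))):
                _place_region(int(rng.integers(iv.start, iv.end)), _direction_sign())

        # expression trajectories
        for gene, linked, active in tad_genes:
            if not active:
                amplitude, true_class = 0.0, "null"
            elif responsive and linked:
                amplitude, true_class = cfg.effect_linked, (
                    "activated" if cls == "up" else "repressed"
                )
            elif responsive:
                amplitude, true_class = cfg.effect_environment, (
                    "activated" if cls == "up" else "repressed"
                )
            else:
                amplitude, true_class = 0.0, "null"
            noise = rng.normal(0.0, cfg.noise_sd, size=t_arr.size) if cfg.noise_sd else np.zeros(t_arr.size)
            l2fc = sign * amplitude * ramp + noise
            padj = _padj(np.abs(l2fc), cfg.noise_sd)
            for t, v, q in zip(t_arr, l2fc, padj):
                expr_rows.append(
                    {
                        "gene_id": gene.gene_id,
                        "timepoint": float(t),
                        "log2fc": float(v),
                        "padj": float(q),
                    }
                )
            gene_rows.append(
                {
                    "gene_id": gene.gene_id,
                    "tad_id": tad_id,
                    "linked": linked,
                    "true_class": true_class,
                    "active": active,
                }
            )

    truth_genes = pd.DataFrame.from_records(gene_rows)
    expression = pd.DataFrame.from_records(expr_rows)

    # count matrix: active genes well covered, inactive genes sparse
    count_rows = []
    active_map = dict(zip(truth_genes["gene_id"], truth_genes["active"]))
    for gene in genes:
        if active_map[gene.gene_id]:
            row = rng.poisson(50.0, size=cfg.n_samples)
        else:
            row = rng.binomial(1, 0.2, size=cfg.n_samples) * rng.poisson(
                2.0, size=cfg.n_samples
            )
        count_rows.append([gene.gene_id, *row.tolist()])
    counts = pd.DataFrame(
        count_rows, columns=["gene_id"] + [f"s{i + 1}" for i in range(cfg.n_samples)]
    ).set_index("gene_id")

    truth = SimTruth(tad_classes, truth_genes)
    data = SimData(
        cfg, chrom_sizes, tads, regions, genes, interactions, expression, counts, truth
    )
    if outdir is not None:
        _write(data, Path(outdir))
    return data


def _write(data: SimData, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    tio.write_tads(outdir / "tads.bed", data.tads)
    tio.write_regions(outdir / "regions.bed", data.regions)
    tio.write_bedpe(outdir / "interactions.bedpe", data.interactions)
    tio.write_genes(outdir / "genes.tsv", data.genes)
    data.expression.to_csv(outdir / "expression.tsv", sep="\t", index=False)
    data.counts.to_csv(outdir / "counts.tsv", sep="\t")
    pd.DataFrame(
        {"tad_id": list(data.truth.tad_classes), "class": list(data.truth.tad_classes.values())}
    ).to_csv(outdir / "truth_tads.tsv", sep="\t", index=False)
    data.truth.genes.to_csv(outdir / "truth_genes.tsv", sep="\t", index=False)
    manifest = {
        "config": asdict(data.config),
        "chrom_sizes": data.chrom_sizes,
        "n_tads": len(data.tads),
        "n_regions": len(data.regions),
        "n_genes": len(data.genes),
        "n_interactions": len(data.interactions),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def truth_vs_inferred(
    truth: SimTruth,
    activities: Sequence[TadActivity],
    responses: Sequence[GeneResponse],
) -> dict:
    """Recovery report: confusion matrices and per-class precision/recall.

    TAD side: latent up/down/neutral against inferred up/down/balanced/
    unscored. Gene side: latent activated/repressed/null against the
    classifier calls. Also reports ``tad_direction_error``: the fraction of
    latent up/down TADs assigned the *opposite* direction (a balanced or
    unscored call counts as uninformative, not as a direction error).
    """
    act_ids = {a.tad_id for a in activities}
    unknown = act_ids - set(truth.tad_classes)
    if unknown:
        raise ValueError(f"activities reference TADs absent from truth: {sorted(unknown)[:5]}")
    resp_ids = {r.gene_id for r in responses}
    unknown_g = resp_ids - set(truth.genes["gene_id"])
    if unknown_g:
        raise ValueError(f"responses reference genes absent from truth: {sorted(unknown_g)[:5]}")

    tad_conf = pd.crosstab(
        pd.Series({a.tad_id: truth.tad_classes[a.tad_id] for a in activities}, name="true"),
        pd.Series({a.tad_id: a.category for a in activities}, name="inferred"),
        dropna=False,
    )

    call_map = dict(zip(truth.genes["gene_id"], truth.genes["true_class"]))
    gene_conf = pd.crosstab(
        pd.Series({r.gene_id: call_map[r.gene_id] for r in responses}, name="true"),
        pd.Series({r.gene_id: r.call for r in responses}, name="inferred"),
        dropna=False,
    )

    def _pr(conf: pd.DataFrame, label: str) -> dict:
        tp = conf.loc[label, label] if label in conf.index and label in conf.columns else 0
        truth_n = conf.loc[label].sum() if label in conf.index else 0
        called_n = conf[label].sum() if label in conf.columns else 0
        return {
            "recall": float(tp / truth_n) if truth_n else float("nan"),
            "precision": float(tp / called_n) if called_n else float("nan"),
            "n_true": int(truth_n),
        }

    n_directional = 0
    n_wrong_direction = 0
    opposite = {"up": "down", "down": "up"}
    for a in activities:
        cls = truth.tad_classes[a.tad_id]
        if cls in opposite:
            n_directional += 1
            if a.category == opposite[cls]:
                n_wrong_direction += 1

    return {
        "tad_confusion": tad_conf,
        "gene_confusion": gene_conf,
        "tad_recovery": {c: _pr(tad_conf, c) for c in ("up", "down")},
        "gene_recovery": {c: _pr(gene_conf, c) for c in ("activated", "repressed")},
        "tad_direction_error": (n_wrong_direction / n_directional) if n_directional else float("nan"),
    }
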