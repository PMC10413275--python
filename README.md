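# tadresponse

Analysis of **regionalized transcriptional responses within topologically
associating domains (TADs)** after glucocorticoid stimulation.

When a hormone such as dexamethasone activates the glucocorticoid receptor,
transcriptional coregulators (MED1, BRD4) are redistributed across the
genome: some cis-regulatory regions gain occupancy, others lose it. This
package asks whether those gains and losses are *regionalized* — whether a
gene's TAD environment, and not only direct contact with a differential
region, predicts its expression response.

It is aimed at regulatory genomicists who already have the upstream
products in hand (differential-occupancy region tables, TAD calls,
significant Hi-C interactions, per-timepoint differential-expression
tables) and want the downstream integration, scoring and statistics as a
tested, scriptable library.

## The model

For each TAD with at least one differential region, the **TAD score** is

```
score = n_gain / (n_gain + n_loss)
```

over the regions assigned to it (by region midpoint). Scored TADs are
classified **up** (score ≥ 0.7), **down** (score ≤ 0.3) or **balanced**;
up and down TADs are called *responsive*. Bimodality of the score
distribution — the signature of regionalized, direction-consistent
redistribution — is assessed with Hartigan & Hartigan's **dip statistic**
(implemented from scratch via the greatest-convex-minorant /
least-concave-majorant algorithm) with a seeded Monte-Carlo uniform null,
`p = (exceedances + 1) / (n_null + 1)`.

Genes are called **activated** or **repressed** when, at some timepoint in
the 0.5–6 h course, BH-adjusted p < 0.05 *and* |log2FC| > 0.75 (same row);
genes failing a read-count activity filter (≥ 1 read in 60% of samples)
are **inactive** and excluded. Differential regions are linked to genes
through GREAT-style *basal plus extension* regulatory domains (5 kb up /
1 kb down, extension capped at 10 kb) or through chromatin interactions
whose other anchor covers the promoter (TSS ± 2.5 kb).

The statistical battery mirrors the study design: a permutation test of
regulated genes within responsive TADs (add-one empirical p), Fisher exact
tests (activated × up, repressed × down), chi-squared association of gene
direction with TAD category with Pearson residuals (|r| > 2 flags cells),
and per-timepoint Mann–Whitney comparisons of linked versus unlinked
genes, BH-corrected.

A first-class synthetic-data generator (`tadresponse.simulate`) emits
seed-deterministic datasets with the full latent structure (TAD classes,
class-conditional region directions, linked/environment gene effects) plus
truth tables for recovery testing.

## Worked example

```python
from tadresponse import SimConfig, simulate, TadResponseModel

data = simulate(SimConfig(seed=1))              # ~250 TADs, ~1,000 genes
results = TadResponseModel.from_simulation(data).fit(seed=1)
print(results.summary())
```

prints

```
TAD regionalized-response analysis
==================================================
genes: 1052  (activated 263, repressed 119, unchanged 560, inactive 110)
regions: 383  region-gene links: 202
TADs: 257  scored: 102 (39.7%)
TAD categories: up 61, balanced 17, down 24
dip test of score bimodality: dip 0.0833, p = 0.001 (n = 102)
regulated genes in responsive TADs: 278 (72.8%)
  of which linked to a differential region: 50.0%
permutation enrichment: observed 278, n_perm 10000, p = 0.0001
Fisher activated_x_up: OR = 57.98, p = 3.33e-106
Fisher repressed_x_down: OR = 73.54, p = 1.67e-60
chi-squared (all): chi2 = 232.26, df = 2, p = 3.68e-51
chi-squared (linked): chi2 = 113.64, df = 2, p = 2.1e-25
chi-squared (unlinked): chi2 = 120.59, df = 2, p = 6.52e-27
occupancy-expression correlation (t = 1 h): r = 0.634, p = 1.49e-22, n = 188
```

Reading it: about 40% of TADs received at least one differential region;
their scores are bimodal (dip p at the Monte-Carlo floor), most scored
TADs are up, and 72.8% of regulated genes sit inside a responsive TAD —
far more than gene resampling expects (permutation p ≈ 1/10,001). The
chi-squared tests show the direction match (activated genes in up TADs,
repressed in down TADs) holds both for genes directly linked to a
differential region and for unlinked genes, i.e. the TAD environment
carries signal of its own, while the correlation and the linked/unlinked
amplitude comparison (in `results.timecourse_linked`) show the direct
contact still produces the stronger response.

`results.save(outdir)` writes every intermediate table (gene calls, TAD
activity ranking, links, association-plot data, time-course comparisons)
plus `summary.json`. The same analysis runs from the shell:

```bash
tadresponse simulate --outdir sim --seed 1
tadresponse run-all --regions sim/regions.bed --tads sim/tads.bed \
    --genes sim/genes.tsv --expression sim/expression.tsv \
    --interactions sim/interactions.bedpe --counts sim/counts.tsv \
    --outdir results --seed 1
tadresponse report --results results
```

(`classify-genes`, `link-regions`, `score-tads`, `enrich`, `timecourse`
run the individual stages; `run-all` also accepts a YAML config with every
parameter.)

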