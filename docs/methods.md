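# Methods

This note documents the model implemented by `tadresponse`, the choices
made where several reasonable definitions exist, what the synthetic-data
generator does and does not emulate, and the package's numerical
conventions. Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Coordinates and data model

All coordinates are 0-based, half-open (BED convention); GTF input
(1-based, inclusive) is converted on read, with the TSS taken as `start`
for `+` genes and `end` for `-` genes. Differential regions carry an
occupancy log2 fold change (stimulated vs control) and an adjusted
p-value; the gain/loss direction is strictly the sign of the fold change,
so a zero fold change is rejected at construction. The differential table
is treated as already thresholded upstream (the occupancy analysis used
FDR < 5%); a loader flag can re-apply a cutoff. Non-standard chromosomes
(scaffolds, alternates, chrM) are dropped by default with a configurable
pattern. TADs must be pairwise non-overlapping per chromosome and this is
validated at load time.

## Gene response calls

A gene is **activated** if at any assayed timepoint (0.5–6 h) its
BH-adjusted p-value is below `alpha` (default 0.05) *and* its log2 fold
change exceeds `lfc_up` (default 0.75, strict inequality); **repressed**
symmetrically below `lfc_down` (−0.75). Both conditions must hold in the
same row — a gene significant at one timepoint and strongly changed only
at another is not called. This same-row reading is an interpretation
choice; the alternative (conditions met at any, possibly different,
timepoints) would only enlarge the called sets.

Genes with fewer than `active_fraction` (0.6) of samples carrying at least
`min_reads` (1) reads are **inactive** and excluded from every downstream
set, including the enrichment universe. Missing adjusted p-values are
treated as non-significant, matching the NA output of differential
expression tools under independent filtering. A gene qualifying in both
directions across the course is resolved by majority of qualifying
timepoints, ties by the larger maximum |log2FC|, and flagged `ambiguous`;
the rule is deterministic and order-invariant.

## Regulatory domains and region–gene links

Basal-plus-extension domains: a strand-aware basal window
`[TSS − 5 kb, TSS + 1 kb)` (mirrored on `-`), each edge extended outward
to the nearest neighbouring gene's basal edge, capped at 10 kb beyond the
basal edge. The cap is measured from the basal edge, not the TSS (the
cited assignment tool's semantics); a neighbouring basal domain that
already overlaps the gene's own basal window stops the extension without
ever shrinking the domain below the basal window. The nearest obstruction
is found among *all* genes with smaller (resp. larger) TSS, not only the
adjacent one, because basal windows are strand-asymmetric. Domains are
clipped to `[0, chromosome length)`.

A **linear** link requires ≥ 1 bp overlap between region and domain
(maximal sensitivity, matching common practice); an **interaction** link
requires one anchor of a significant chromatin interaction to overlap the
region and the other to overlap a promoter window of TSS ± 2.5 kb. The
promoter half-width is not dictated by any upstream convention and is
exposed in `LinkConfig`. Links are deduplicated per (region, gene,
evidence); multiplicity counts distinct regions per gene, stratified
`1` vs `2+`.

## TAD scoring and classification

Regions are assigned to the TAD containing their floor midpoint, genes by
TSS containment (both half-open) — single, unambiguous assignments for
boundary-spanning features. Per TAD, `score = gain / (gain + loss)`;
category **up** iff score ≥ 0.7, **down** iff ≤ 0.3 (both inclusive),
**balanced** strictly between, **unscored** when the TAD has no region.

## Dip statistic and Monte Carlo test

The dip — the smallest sup-norm distance from the empirical CDF to any
unimodal distribution function — is computed from scratch with the
greatest-convex-minorant / least-concave-majorant algorithm on the sorted
sample, in exact count arithmetic (ties handled without jitter; a
deterministic rank-epsilon jitter utility was considered and rejected as
unnecessary once the tied-data path was exact). For a sample with at least
two distinct values the dip is bounded below by `1/(2n)`; a constant
sample is itself unimodal and returns 0. The implementation is verified
against an independent brute force based on the excess-mass
characterisation (dip = half the maximal two-interval excess-mass gain,
a finite maximisation over interval pairs and envelope crossings); a
direct minimisation over unimodal CDFs is not a finite linear program
because a mode interior to a sample gap couples the straddling segment
through a slope × width product.

The p-value is Monte Carlo against uniform(0, 1) nulls of the same sample
size — the asymptotically least-favourable unimodal null — with the
add-one estimator `(exceedances + 1)/(n_null + 1)`, exactly reproducible
from a seed and bounded below by `1/(n_null + 1)`. Interpolated lookup
tables would be faster but are not seed-reproducible; with the default
`n_null = 999` the smallest reportable p is 1e-3, so a run can report a
floor value rather than the astronomically small p an asymptotic
approximation might print.

## Enrichment battery

* **Permutation test**: statistic = number of query (regulated) genes in
  responsive TADs; null = gene sets of equal size resampled uniformly
  without replacement from the non-inactive, TAD-assigned universe. Since
  the count statistic of such a draw is exactly hypergeometric, the null
  is sampled through `rng.hypergeometric` — the identical distribution
  without materialising permutations. A second variant
  (`shuffle="tads"`) permutes responsive labels across TADs, preserving
  the gene–TAD clustering; the gene-resampling variant is the default and
  the one the reported p-values use.
* **Fisher 2×2**: exact two-sided p; odds ratio reported as the sample
  cross-product (∞ when a margin cell is empty, with the Haldane–Anscombe
  +0.5 value alongside). Conditional-MLE odds ratios from other
  environments differ slightly in the point estimate, not the p-value.
* **Chi-squared**: no Yates correction, so that χ² equals the sum of
  squared Pearson residuals exactly (the identity the association plot
  uses); cells with |residual| > 2 are flagged enriched/depleted. Raised
  on zero margins.
* **Mann–Whitney**: exact enumeration when both groups have ≤ 8
  observations and no ties; otherwise the normal approximation with tie
  and continuity corrections. Time-course comparisons run one test per
  timepoint with BH correction across the (seven) timepoints and the
  ns/*/**/*** star encoding.

The model-level time-course comparison contrasts |log2FC| of linked vs
unlinked regulated genes within responsive TADs (amplitudes pooled across
up and down TADs; per-category signed trajectories are available through
the saved tables).

## Synthetic data generator

The generator emulates the *structure* the analysis assumes, at desk
scale. Defaults are the study conditions where stated, otherwise values a
genomicist would call realistic, chosen once:

| parameter | default | rationale |
|---|---|---|
| chromosomes × length | 5 × 40 Mb | ~250 TADs, minutes-scale runs |
| TAD size | log-normal, mean 800 kb, sd 400 kb | genome/TAD-count ratio of the study |
| p_up, p_down | 0.28, 0.09 | 37% responsive TADs with the reported up:down imbalance |
| regions per responsive TAD | Poisson(3.4), min 1 | the study's reported average |
| P(gain) in up / down TADs | 0.9 / 0.1 | strong class-conditional direction |
| genes per TAD | Poisson(4) | ~20k genes over ~5k TADs |
| P(linked) in responsive TADs | 0.4 | the reported linked fraction |
| effect linked / environment | 2.0 / 0.6 log2FC | contact effect > environment effect |
| noise sd | 0.3 per timepoint | clear but not trivial separation |
| interaction fraction | 0.25 | minority of links wired in 3D |
| inactive gene fraction | 0.1 | exercises the activity filter |

Trajectories follow a saturating ramp `1 − exp(−t/1.2 h)` (plateau by
2–3 h); the kinetics are invented, only the ordering of amplitudes
matters. Adjusted p-values are a deterministic monotone map of
`|log2FC| / noise_sd` (two-sided normal tail) — sufficient to exercise the
classifier thresholds, *not* a fitted DE model: it lacks BH correction
across genes, dispersion, and count-level noise. Neutral TADs receive no
differential regions by default, making "unscored" the neutral signature;
`background_region_rate` sprinkles noise regions for stress tests.
TADs tile each chromosome contiguously, so no gene or region is ever
unassigned — inter-TAD gaps of real Hi-C segmentations are not emulated
(the assignment code handles gaps; the generator simply does not produce
them). Consequently, passing recovery tests demonstrate the pipeline's
correctness on data satisfying its assumptions, not robustness to
assembly gaps, nested/overlapping TAD calls, or occupancy-dependent
region widths.

`truth_vs_inferred` reports confusion matrices, per-class
precision/recall, and a direction-error rate for latent up/down TADs
(fraction assigned the *opposite* direction; balanced or unscored calls
count as uninformative, not as direction errors). The distinction
matters: with ~4 regions per TAD and a 0.7 threshold, a 3-region up TAD
needs all three gains to clear 0.7, so even at P(gain) = 0.95 the
expected plain recall is ≈ 0.94 — an arithmetic property of the score
grid, not an inference failure — while direction errors stay below 1%.

## Determinism and seeds

Every stochastic step consumes a `numpy` Generator seeded from the global
seed forked per stage by stable SHA-256 name hashing (`stage_seed`), so
adding a stage never perturbs earlier stages' draws and re-runs are
bit-identical. The generator's file output is byte-identical per seed.

## Problem sizes used by the shipped checks

The test suite and acceptance script run at desk scale, chosen as the
smallest sizes at which each property is sharply testable: the dip oracle
battery at n ≤ 8 (the brute force is O(m⁸)); dip-test calibration at 200
uniform replicates of n = 100 with 999 nulls; permutation calibration at
1,000 datasets over a universe of 8,000 genes in 2,000 TADs; parameter
recovery on ~500 TADs. The study-scale count consistency (4,957 TADs,
1,759 genes) runs directly, in seconds.

## Known limitations

* The permutation and dip p-values bottom out at `1/(n+1)`; environments
  using asymptotic approximations can print far smaller values for the
  same data.
* The chi-squared battery requires non-degenerate margins; strata with an
  empty row/column (e.g. no repressed genes among linked) are skipped
  rather than patched.
* `signal_expression_correlation` takes whatever region-level value the
  caller supplies (the model uses the occupancy log2FC at the earliest
  timepoint ≥ 1 h); with read-density inputs the choice of density versus
  its change is the caller's and is recorded in the output metadata.
* The generator draws each gene's linkage independently; it does not
  emulate multi-gene regulatory hubs, distance-dependent interaction
  probabilities, or chromatin-state segmentation (state-overlap profiling
  is exercised on constructed segmentations in the unit tests instead).
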