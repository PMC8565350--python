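# Methods

## Colocalization model

Each experimental condition (one buffer/lipid/DNA setting) contributes one
or more two-channel fields of view: a liposome channel (membrane dye) and
a DNA channel (DNA-conjugated fluorophore). Liposome pixels are identified
by a single intensity threshold per condition,

    threshold = mean + 2 * SD,

where mean and SD are computed over the pooled pixel population of the
liposome channel across *all* images of the condition. Pooling assumes
images within a condition share illumination and exposure; the SD is the
population SD (denominator N) and a pixel is liposome iff strictly above
the threshold, so the rule is exactly reproducible and order-invariant.
No morphological clean-up is applied by default (an optional minimum
object size exists); nothing is excluded by default (flags exist for
saturated pixels and image borders).

The colocalization ratio of an image is the mean DNA intensity over mask
pixels divided by the mean over the strict complement. Raw intensities are
used — no background subtraction or flat-field — because the statistic is
deliberately ratiometric: multiplying the DNA channel by any k > 0 leaves
C_R unchanged, while an additive offset does change it (both properties
are tested). C_R is computed per image and summarized per condition as
mean ± sample SD over images. Manders M1/M2 overlap fractions and
Pearson's pixel correlation are emitted as auxiliary metrics; Pearson is
retained specifically to demonstrate its area bias (below).

## Synthetic imaging data

The generator emulates TIRF fields of surface-tethered extruded vesicles:

- Liposomes are hard disks (radius ~ N(6, 1) px truncated positive)
  placed by rejection sampling with no overlap and a 1 px gap;
  infeasible packings raise an explicit error after 10,000 attempts.
- The liposome channel is the two-level disk image (foreground 4000,
  background 500 on a 16-bit scale) convolved with a Gaussian of σ = 1 px
  as a diffraction proxy — the simplest rendering that makes thresholding
  non-trivial.
- The DNA channel is a sharp two-level field: mean `dna_bg_mean` (1000)
  outside the true disks and `enrichment_rho ×` that inside. Enrichment is
  defined on mean intensity, matching the C_R definition, so
  `enrichment_rho` is the ground truth for C_R; rho = 1 makes the DNA
  channel statistically independent of liposome positions.
- Noise is additive Gaussian with SD 5% of the channel background by
  default (EMCCD images at these levels are approximately Gaussian);
  Poisson shot noise is available. Pixels are rounded and clipped to the
  bit depth, and the clipped fraction is reported; defaults sit far from
  saturation, with saturation reachable as a stress scenario (e.g. 8-bit
  with foreground above 255).
- Optional per-image enrichment jitter (`enrichment_jitter_sd`, default
  0) draws each image's realized enrichment from
  N(rho, jitter); realized values are recorded in the ground truth. Real
  condition sets show substantial image-to-image C_R spread, and validation
  suites that regress metrics on coverage need that realistic variance —
  with zero jitter the per-image C_R noise is ~10⁻³ and a 95% CI on a
  metric-vs-coverage slope resolves segmentation edge effects at the same
  scale, which no threshold-based mask is free of.

Default geometry (40 disks of radius 6±1 in 256×256, ≈7% coverage) was
chosen so the pooled threshold lands near the half-maximum of the blurred
disk edge: the pooled mean+2·SD of a two-level image with cover fraction c
sits at a fraction ≈ c + 2·sqrt(c(1−c)) of the foreground step, which
crosses the 0.5 edge level around c ≈ 5–7%. In this regime the mask tracks
the true disks (Jaccard ≈ 0.99) and condition mean C_R recovers the
generating enrichment to ~0.1%. The area-bias suite
(`area_bias_suite_scenario`) instead uses radius 5 and counts 5–80 in a
*single* condition: one pooled threshold then sits slightly below the
half-edge level for every image, so masks capture whole liposomes at every
count and C_R has no systematic coverage dependence, while Pearson's r
rises strongly with coverage.

The generator does not model physical optics (no vectorial PSF, no
evanescent-field depth), liposome diffusion or time series, 3D confocal
geometry, aggregation, or batch (vesicle-prep) effects. Passing tests
therefore demonstrate correctness of the quantification given the stated
image model, not robustness to those real-data complications.

## Gel model and densitometry

A synthetic gel renders paired lanes on a uniform background: the
migrating tile band is a Gaussian profile along the migration axis
(amplitude 3000, σ = 6 px) uniform across the lane; in the +liposome lane
the band amplitude is multiplied by (1 − f) for bound fraction f and the
bound signal is placed in the well region at the top of the lane (bound
structures do not enter the matrix). Per-lane loading is multiplicative
N(1, loading_cv) applied to the loaded material only; the default
loading_cv of 2% reflects pipetting accuracy under a protocol where
replicate gels are averaged — real gel-to-gel spreads are larger because
they include liposome-prep variability, which is out of scope here.

Band integration sums the annotated band box and subtracts
`median(flanking pixels) × box area`, with flanking boxes of identical
size directly above and below the band. The median makes the background
estimate robust to the band's own Gaussian tails and to specks. Corrected
integrals are floored at zero with a warning. Both corrected (primary)
and raw integrals are reported. Lane boxes are user-supplied annotations;
automatic lane/band detection is out of scope.

T may be negative when loading noise pushes B above U; it is reported
as-is with a warning rather than clamped, so replicate averaging remains
unbiased. T is invariant under global exposure scaling.

## Occupancy regression

Observed band fluorescence versus designed handle count n is linear only
at low n. The fit uses the n ≤ 4 points: the intercept is tied to the
mean of the n = 0 measurements (it estimates label-independent
background, which the n = 0 lane measures directly), and the slope is
least squares through the origin on the deviations. The apparent occupied
count at the nominal n is (observed − intercept)/slope, and the 95% CI
propagates the observation, intercept and slope variances (delta method,
homoscedastic residual variance, t critical value with
df = n_fit_points − 1). A non-positive slope is an error: occupancy is
undefined without signal gain per handle. With noiseless input the CI has
zero width. Coverage simulations (200 replicates at true occupancy 0.7,
5% measurement noise) show ≥ 90% CI coverage.

## Statistics

- `trend_test`: OLS on per-image metric versus condition variable
  (per-image is the default unit; per-condition means can be passed
  instead). The 95% CI uses the t distribution with n − 2 df; a perfect
  fit yields a zero-width CI. Decision rule: increasing iff CI low > 0,
  decreasing iff CI high < 0, otherwise no trend.
- `rank_sum_compare`: two-sided Mann–Whitney/Wilcoxon. Exact enumeration
  when both groups have ≤ 20 observations and the pooled sample is
  tie-free; otherwise the tie-corrected normal approximation with
  continuity correction. All-identical pooled values short-circuit to
  p = 1. Unadjusted p-values are primary (Holm adjustment available as
  `holm_adjust`).
- `pooled_summary`: mean ± sample SD over per-image values concatenated
  across conditions, with exclusion by name or predicate (e.g. dropping a
  denaturing pH condition from a pooled binding figure).

## Pipeline

`lipoquant run` executes simulate → segment → coloc → gel → stats from one
YAML config. Stage seeds are derived as SHA-256(master_seed:stage_name)
mod 2³¹, so stages have independent reproducible streams. The run report
records the canonical config hash and SHA-256 of every artifact; rerunning
a downstream stage does not mutate upstream outputs.

## Problem sizes

Tests and the acceptance script use 256×256 fields (8–14 per condition),
single-pair gels, 200-replicate occupancy coverage simulations and
1000-replicate calibration simulations for the rank-sum type-I error and
trend-CI coverage — sizes at which Monte-Carlo error is comfortably below
the tested tolerances while a full run stays in the seconds-to-minutes
range.

## Known limitations

- The threshold rule assumes a roughly unimodal background plus a bright
  minority population; it degenerates when coverage approaches ~25%,
  where mean + 2·SD can exceed the foreground level.
- The background region is the strict mask complement; no guard band is
  excluded around liposomes, so diffraction halos slightly dilute
  enrichment in real images (not modelled by the sharp DNA step).
- Occupancy CIs assume homoscedastic noise across handle counts.
- Gel quantification assumes a single well-separated band per lane;
  smears, aggregates and molecular-weight calibration are out of scope.
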