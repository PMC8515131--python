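# Methods

## Problem and quantities

Breast DCE-MRI acquires one pre-contrast fat-suppressed T1 volume and three
post-contrast volumes timed at 60, 180 and 300 s (k-space centre time).
Three subject-level quantities summarise the normal parenchyma:

* **FGT** = V_fibroglandular / V_breast — the volume fraction of
  fibroglandular tissue in the whole breast;
* **BPE_V**(t) = V_enhanced-FGT / V_FGT — the fraction of FGT that enhances
  at phase t;
* **BPE_I**(t) = mean over enhanced-FGT voxels of
  I_subtraction / I_original — the enhancement intensity ratio.

Voxel volume is constant within a series, so both volume ratios are computed
as voxel-count ratios. To avoid lesion contamination, the subject-level
measurement is the metric-wise mean of the two breasts in controls and the
contralateral breast (verbatim) in subjects with a unilateral lesion. The
control-group "mean" is taken at the metric level, not by pooling voxels
across breasts; with equal-sized breasts the two differ negligibly, and the
metric-level mean is well defined even when breast volumes differ.

## Measurement pipeline

**Step 1 — whole breast.** On each 2D slice two one-row-per-column paths are
traced by dynamic programming: the chest wall and the skin line. A path
minimises `Σ cost + λ_smooth Σ|Δrow| + λ_prior Σ|row − prior_row|` globally,
with the per-column step bounded by `smoothness_limit` (default 12) and the
prior taken from the adjacent, already-traced slice (continuity across
slices). Slices are processed middle-out starting from the slice with the
most foreground, where both boundaries are fully developed. The cost map is
`1 − g/(g+g0)` on the Sobel gradient magnitude g of the lightly smoothed
slice, with `g0` twice the median gradient: this saturating transform puts
every genuine edge near zero cost and leaves noise expensive, so the choice
*between* edges is made by a small posterior bias (0.1 over the row range)
and the band constraints, not by edge contrast. The chest-wall search is
restricted to the posterior 35% of the foreground row extent; the skin
search runs on the gradient of the tissue/air outline (Otsu on smoothed
log-intensities) and is excluded from a 2-row halo above the traced chest
wall. The breast mask is the band between the paths, intersected with the
once-eroded foreground (smoothing before Otsu dilates the tissue surface by
about one voxel; the erosion restores an unbiased surface — measured on
noiseless phantoms, this halves the surface error and removes a ≈ −1 point
bias in the FGT fraction). Columns thinner than 4 voxels are background;
the mask splits left/right at the minimum-foreground column near the volume
centre. Defaults: `λ_smooth = 0.05`, `λ_prior = 0.02` on the unit-scaled
cost. Ties in the DP are broken toward the smaller row index, making the
tracer fully deterministic. The chest wall and skin line are traced
separately (chest first, skin constrained anterior of it).

**Step 2 — FGT.** Fuzzy c-means on the pooled 3D intensities inside the
breast mask (not per slice), fuzzifier m = 2, relative objective tolerance
1e-5, ≤ 300 iterations, centroids initialised at evenly spaced intensity
quantiles (deterministic; the relative stopping rule makes centroids exactly
scale-equivariant). The cluster number is chosen in 2–5 by minimising the
Xie-Beni index (selection runs on a 30k-voxel seeded subsample for speed;
the final fit uses all voxels). Clusters with centroid above the midpoint of
the extreme centroids are FGT — on fat-suppressed T1 the gland is the bright
class. When the centroid spread is below half the brightest centroid the
breast is considered gland-free (fat + skin only) and the FGT mask is empty;
without this guard an all-fat breast would always donate its brightest
cluster (the skin shell) to FGT.

**Step 3 — enhanced FGT.** Subtraction volume = post − pre, unclipped. The
noise level σ is 1.4826·MAD of subtraction values in a non-enhancing
reference region (breast minus FGT, i.e. fat; whole breast as fallback),
robust to contaminating enhancement. Enhanced FGT = FGT voxels with
subtraction > k·σ, with k = 3 by default (the conventional noise floor; the
threshold is global, not per-slice). No morphological cleanup is applied.

**BPE_I guard.** Voxels whose pre-contrast intensity is below 1% of the
volume's median absolute intensity are excluded from the BPE_I mean (the
ratio divides by I_original); exclusions are counted and warned about.
Subjects with an empty FGT mask yield flagged NaN metrics and are dropped
listwise from the statistics.

## Statistics

Group contrasts (cancer vs control, cancer vs benign) per metric, menopause
stratum and phase use the two-sided Mann-Whitney U test: exact enumeration
when n1+n2 ≤ 12 and the pooled sample is tie-free, tie-corrected normal
approximation with continuity correction otherwise. Discrimination is the
empirical (pair-counting) AUC with ties half-weighted, computed via midranks
— algebraically identical to U/(n1·n2) — with the cancer group as positive
class and the direction reported as computed (not folded above 0.5). Group
summaries are medians, consistent with the rank test. No multiple-testing
correction is applied. Matching is greedy: cases in ascending age order take
their nearest-age candidate with the same menopause status (and menstrual
week when premenopausal) within 5 years; ties break on the lowest subject
id; unmatched cases are reported, not fatal.

## Phantoms

Each phantom is two hemiellipsoidal breasts (semi-axes 1.7r × 2.0r × r,
default r = 20 mm) resting on a flat chest-wall slab (default 12 mm), with a
one-voxel skin shell and air elsewhere; the default grid is 96³ at 1 mm
isotropic spacing. Fat-suppressed T1 intensities are piecewise constant by
class — air 5, fat 60, skin 90, muscle 130, gland 220 — with additive
Gaussian voxel noise (default σ = 5; Rician optional). The skin intensity
sits below the fat/gland midpoint so the shell classes with fat, as thin
skin largely does after fat suppression.

FGT is a compact core of exactly `round(f·N_breast)` voxels per breast,
grown from a centre displaced anteriorly (0.45 of the anterior semi-axis)
so the gland does not abut the chest wall. Enhancement takes a seeded random
permutation of FGT voxels and enhances the first `round(e_p·N_FGT)` at phase
p — per-phase masks are therefore nested, and monotone kinetics follow from
monotone fractions. Post-contrast volumes multiply enhanced voxels by
(1 + ratio_p), making the true BPE_I analytically equal to ratio_p and the
true FGT/BPE_V exact voxel-count ratios.

Cohorts reproduce the study structure: 132 subjects per group (control,
benign, cancer), 62 premenopausal with menstrual-week strata 13/16/15/18,
70 postmenopausal. Per-subject true metrics are logit-normal around the
published group medians (guaranteeing values in (0,1); the tables are read
as medians, consistent with the rank-based testing). The logit-scale spread
is derived from the published AUC of each stratum's most discriminative
phase through the binormal identity σ = Δlogit-median / (√2·Φ⁻¹(AUC)), so
the generator reproduces both the locations and the discriminability of the
groups. Within a subject, one latent score per metric is shifted by the
per-phase median offsets — per-phase medians are exact and kinetics stay
monotone; metrics are drawn independently of each other. Ages are uniform
integers within the published per-group ranges. Recovery cohorts sample the
latent scores at evenly spaced quantiles (stratified) instead of iid, so
the cohort median equals the construction median exactly and median
recovery error isolates the measurement pipeline.

What the phantoms do *not* emulate: MR physics (relaxometry, coil bias
fields), motion, anatomical texture, lesions as image objects (laterality
is metadata only), or correlated noise. Passing recovery tests therefore
demonstrates the internal consistency of the segmentation and statistics on
geometry with known truth, not performance on clinical images.

## Problem sizes and tolerances

The test suite runs recovery at n = 16 phantoms on 64³ grids; the
acceptance script runs n = 40 on 96³ grids. Stratified sampling makes the
cohort median scale-invariant, so the smaller suite checks the same
property. Measured medians recover the construction targets to ≈ 0.2 points
(FGT) and ≈ 1.2 points (BPE_V, dominated by a small FGT-boundary
over-inclusion that inflates the BPE_V denominator). Dice against truth is
≈ 0.99 noiseless and ≈ 0.97 at twice the default noise, degrading
monotonically. The DP tracer is verified against exhaustive path
enumeration, FCM against a grid-search oracle, the AUC against brute-force
pair counting and the U-statistic identity, and the Mann-Whitney p against
full enumeration and a type-I calibration at α = 0.05.

## Known limitations

* The skin shell is counted as breast in the truth masks but classes as fat
  in step 2; very high skin intensities would leak into FGT.
* The chest-wall band assumes a roughly prone geometry with the chest in
  the posterior 35% of the foreground; other orientations need
  reconfiguration.
* BPE_I is modelled (and generated) in (0,1); enhancement ratios above 1
  are legal for the measurement but not produced by the cohort generator.
* The noise-threshold rule k·σ is a global per-phase threshold; the exact
  statistical rule used clinically may differ (percentiles, per-slice
  levels), and k is configurable for that reason.
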