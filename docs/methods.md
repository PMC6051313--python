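# Methods

## Scaled subprofile model and pattern derivation

All subjects' images must already be co-registered to a common grid; the
package performs no registration or smoothing. The analysis mask keeps
voxels at or above `mask_fraction` (default 0.35) of each scan's own
intensity maximum, intersected across subjects, so only voxels supported
in every scan enter the model. Masked intensities are natural-log
transformed (natural rather than base-10 log; the choice only rescales
weights). Each subject's mean over masked voxels is subtracted first
(removing global scaling exactly: the model is multiplicative in
intensity, additive in log), then the across-subject mean of the
row-centered data — the group mean profile (GMP) — is subtracted. This
order makes both row and column sums of the Subject Residual Profile
(SRP) matrix exactly zero. The GMP is computed from the combined
patients-plus-controls derivation sample, which keeps prospective
single-scan scoring well defined.

PCA is computed through the singular value decomposition of the SRP
matrix, which is numerically stable and identical (to 1e-6, verified
against dense voxel-space and subject-space eigendecompositions in the
tests) to eigendecomposition of the voxel-space covariance. Variance
accounted for (vaf) is the squared singular value over the total sum of
squares, computed over masked voxels only. The double centering leaves at
most n−1 non-null components; null directions are dropped. Eigenvector
signs are fixed by non-negative correlation of subject loadings with the
patient labels (falling back to a positive-peak convention when labels
are absent).

Candidate components are the smallest prefix whose cumulative vaf reaches
`variance_threshold` (default 0.50); a component that lands exactly on
the threshold is included. Selection is stepwise logistic regression
under AIC (AIC = 2k − 2 log L with k counting the intercept): forward
addition with backward pruning, applying at each step the single move
that lowers AIC most, stopping when no move helps. For up to 7 candidates
the tests compare the greedy search against exhaustive enumeration of all
2^7 subsets. Perfectly separated fits are given the supremum
log-likelihood 0 (AIC = 2k) and, if a model separates, the final model
falls back to the best separating single component with coefficients from
a ridge-stabilized fit (L2 penalty 1e-4 on slopes) so downstream
arithmetic stays finite — small cohorts separate often. If stepwise
selection retains nothing (no candidate beats the AIC penalty of 2), the
single candidate with the lowest one-component AIC is used so that
scoring stays defined; the fallback is flagged in the model metadata.

The pattern is the coefficient-weighted sum of the selected components,
rescaled to unit Euclidean norm (the norm is a free scale absorbed by
z-scoring) and signed so patients score higher than controls. The
intercept of the logistic fit is discarded: it shifts all scores equally
and is removed by the control reference. Expression z-scores are
(raw − control mean)/control SD with the n−1 denominator.

## Validation

LOOCV repeats the entire identification — mask, SRP, PCA, stepwise
selection, combination, control reference — on every leave-one-out
subsample and scores the held-out scan through the prospective path. Each
fold's own component count and selection are used; nothing is frozen
across folds. One deliberate convention: a fold's pattern sign is aligned
to the full-cohort pattern by dot product (exactly as bootstrap
replicates are aligned), not re-oriented against the fold's own labels.
Re-orienting per fold folds the null distribution of the group difference
toward positive values and inflates the type-I error of the subsequent
t-test roughly fourfold (measured ~22/100 versus ~5/100 null rejections
at α = 0.05 in the package's own simulations); a single global
orientation bit leaves the two-sided test at its nominal level and does
not change real-effect recovery.

The ROC sweeps all midpoints between adjacent sorted unique scores plus
one cutoff below the minimum and one above the maximum; the optimum
maximizes Youden's J = sensitivity + specificity − 1, with ties broken
toward higher specificity and then toward the lower cutoff. Scores
exactly at the cutoff classify as patient. AUC is the rank-based
(midrank) area, equal to the Mann-Whitney U statistic over n₁n₂. The
published reference cutoff for this pattern type, z = 1.26, is exposed as
`validation.REFERENCE_CUTOFF_Z`.

## Bootstrap stability

Replicates resample subjects with replacement within each group (group
sizes preserved; unstratified resampling can produce single-class draws
on small cohorts). Every replicate reruns the full identification,
including its own mask — a replicate's mask always contains the original
analysis mask, because it intersects per-scan masks over a subject
subset — and is sign-aligned to the original pattern by dot product.
Percentiles use the linear-interpolation empirical convention (stated
because bit-reproducibility depends on it); a voxel is stable-positive if
its (1−level) percentile exceeds zero and stable-negative if its level
percentile is below zero, level defaulting to 0.95. Displayed values at
stable voxels are replicate medians. Failing replicates are redrawn and
counted; more than 20% failures aborts.

Calibration caveat: the stability rule is the union of two one-sided 5%
percentile tests, and because resampling reuses the cohort's realized
voxel noise, the replicate distribution at a truly signal-free voxel
centers near that voxel's observed noise-driven weight. Each side then
operates near its nominal 5% level, so roughly 10% of truly-null voxels
are marked stable under the default conditions — the map thresholding is
a display heuristic, not a 5%-level test. The package's simulations
measure ~10% false stability alongside ~100% retention of true cluster
voxels.

## Clinical and ROI statistics

Group comparisons: pooled-variance t-test for age, chi-square without
Yates correction on the 2×2 sex table, Mann-Whitney U elsewhere (exact
enumeration for combined n ≤ 20 without ties, otherwise the normal
approximation with continuity correction and midranks). Correlations of
expression z-scores with clinical variables use Pearson's r for
approximately normal demographics (age, onset, duration) and Spearman's ρ
(midranks) for ordinal scales (ataxia severity and sub-items, CAG
repeats, education, mood and neuropsychological scores), with
significance at α = 0.005 (0.05 Bonferroni-divided by 10 planned tests).
Variables with fewer than 3 complete pairs, or constant columns, are
reported as skipped, never silently dropped.

The ROI stage sums uptake over each region and divides by the subject's
whole-brain sum ("total uptake" is read as a sum; the denominator mask is
configurable and defaults to the subject's positive voxels), making the
measure exactly invariant to global intensity scaling. Lateralized
region pairs are merged by summation before any statistics. Per region,
Pearson r relates grey-matter volume to normalized uptake, and Spearman ρ
relates ataxia severity and disease duration to both measures, at
α = 0.05 explicitly flagged as uncorrected. Regions are user-supplied
binary masks rather than atlas extractions, so no external atlas is
needed for testing; the generator emits geometric stand-ins named after
the regions of interest in cerebellar disease (brainstem, cerebellar
hemispheres and vermis, caudate, superior frontal).

## Synthetic cohorts

The generator writes the generative model the SSM inverts:
log I_sv = α_s + μ_v + z_s·P_v + ε_sv inside an ellipsoidal brain support
at 60% of the grid extent, with background at 1% of the in-brain mean
(scaled by each subject's global factor, so global rescaling acts on the
whole image). Defaults are the emulated study conditions: 16 controls and
17 patients on a 20³ grid, expression scores z_s ~ N(0, 1) for controls
and N(3, 1) for patients, voxel noise SD 0.05 in log units, global offset
SD 0.1, and a shared mean profile with 0.1 log-SD of smooth spatial
variation (kept mild so the 35% mask retains essentially the whole
support).

The ground-truth pattern is four Gaussian blobs (two positive, two
negative) at jittered canonical positions; values below 5% of the peak
are set exactly to zero before the remaining voxels are mean-balanced
over the support and the field is unit-normed. Hard-zeroing gives the
pattern a genuine null region — without it the blob tails plus
mean-centering leave a little true signal at every support voxel and
"false stability" would not be measurable. Clinical covariates are
generated against the true scores: ataxia totals are a strictly
increasing softplus map of the score plus noise for patients (rounded to
0.5 steps, near zero for controls), split into 8 sub-items dominated by
gait and stance; CAG repeats couple negatively to onset age (ρ ≈ −0.8);
letter fluency declines with expression; the remaining
neuropsychological, mood and demographic variables carry group-level
differences with only weak score coupling. Noise magnitudes were chosen
once to land correlation magnitudes in the 0.5–0.8 range typical of such
cohorts, not to reproduce any specific published value. In the ROI
generator, atrophy variability is modeled only in the cerebellar
structures (vermis coupled to metabolism through a shared severity
factor; hemispheres varying without matching uptake change, as a proper
null), other regions' grey matter being constant across subjects — so
their atrophy–metabolism test is reported as skipped rather than run on
pure noise.

What the synthetic data does not emulate: scanner physics (point-spread,
attenuation, time-activity), misregistration, spatially correlated or
heteroscedastic noise, non-normal expression distributions, and real
anatomical topography. Passing tests therefore demonstrate the
correctness and calibration of the procedure, not its behavior on real
acquisitions.

## Problem sizes and reproducibility

Default analyses run 33 subjects on 20³ grids (~900 masked voxels), with
200 bootstrap replicates in the scripted runs (the percentile maps are
already stable there; the 1000-replicate default of `RunConfig` matches
the published protocol). Null-calibration simulations use 12³ grids and
100 cohorts. One global seed fans out to per-stage seeds via SHA-256 of
`"{seed}:{stage}"` (truncated below 2³¹), so any stage can be reproduced
in isolation; with a fixed configuration and seed the pipeline report is
byte-identical across runs, and the configuration hash stamped into every
output excludes only the output directory.

## Known limitations

- The stepwise search is greedy; it is verified against exhaustive AIC
  enumeration only on well-separated synthetic cohorts (it agrees in
  ≥ 18/20 there, always at > 3 SD separation), not universally.
- The bootstrap stability map's ~10% false-positive rate at null voxels
  (see above) is a property of the percentile rule itself.
- LOOCV z-scores are mutually correlated (folds share n−2 subjects), so
  the group t-test on them is approximate even with the label-free sign
  convention; its null level is verified by simulation, not theory.
- The ROI stage accepts grey-matter density maps as given; no
  segmentation or voxel-based morphometry group inference is provided.
- No handling of missing scans, partial masks differing in shape, or
  DICOM ingestion.
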