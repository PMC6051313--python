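# ssmpca

Derivation and validation of disease-related metabolic covariance patterns
from multi-subject 3D brain images with the scaled subprofile model (SSM)
and principal component analysis — the workflow used to characterize
network-level metabolic changes in neurodegenerative disease from FDG-PET,
e.g. in spinocerebellar ataxia or Parkinson's disease cohorts.

The package is aimed at imaging researchers who want a tested, scriptable
version of the full analysis chain: voxel masking, log double-centering
into Subject Residual Profiles, PCA, stepwise component selection,
expression scoring of individual scans, leave-one-out cross-validation
(LOOCV) with ROC thresholding, bootstrap voxel-stability mapping, and the
clinical / region-of-interest correlation layers. A synthetic-cohort
generator with a known embedded pattern provides ground truth for every
stage, so the whole pipeline is verifiable end to end.

## The model

For subject *s* and voxel *v* inside a common brain mask, the log image is
decomposed as

    log I_sv = m_s + GMP_v + SRP_sv

where *m*<sub>s</sub> is the subject's mean over masked voxels (global
scaling), GMP<sub>v</sub> the group mean profile, and SRP<sub>sv</sub> the
doubly-centered Subject Residual Profile. PCA of the SRP matrix in voxel
space yields orthonormal covariance patterns; the components explaining
the top 50% of variance are candidates, and a stepwise logistic regression
under AIC picks the subset that best separates patients from controls.
The selected components, weighted by their logistic coefficients, form a
single unit-norm pattern **P**. A scan's expression score is the
projection of its residual profile onto **P**,

    score(s) = ⟨ log I_s − m_s − GMP , P ⟩ ,

reported as a z-score against the derivation controls. Validation scores
every subject with a pattern re-derived without that subject (LOOCV); a
Youden-optimal ROC cutoff turns scores into a classification rule; a
within-group bootstrap of the entire derivation maps which voxel weights
are stable (one-sided 95% percentile interval excluding zero).

## Worked example

```python
import numpy as np
from ssmpca import CohortParams, simulate_cohort, build_common_mask, compute_srp
from ssmpca.pattern import derive_pattern, zscore_scores
from ssmpca.validation import loocv, group_ttest, roc_optimal_cutoff, sens_spec

scans, truth, table = simulate_cohort(CohortParams(seed=1))   # 16 controls + 17 patients
labels = table["label"].to_numpy()
mask = build_common_mask(scans, fraction=0.35)
srp = compute_srp(scans, mask, labels)
model, raw = derive_pattern(srp, variance_threshold=0.5)

cv = loocv(scans, labels)
t, p = group_ttest(cv.z_scores, labels)
z = np.array([s.z for s in zscore_scores(raw, model.control_ref, srp.subject_ids)])
roc = roc_optimal_cutoff(z, labels)
sens, spec = sens_spec(cv.z_scores, labels, roc.optimal_cutoff)

print(f"mask voxels:        {mask.n_voxels}")
print(f"components kept:    {model.selected_components} "
      f"(candidates explain {100*sum(model.selection_info['candidate_vaf']):.1f}% variance)")
print(f"pattern vs truth r: {np.corrcoef(model.weights, truth.pattern[mask.keep])[0,1]:.3f}")
print(f"LOOCV t-test:       t = {t:.2f}, p = {p:.2e}")
print(f"ROC cutoff:         z = {roc.optimal_cutoff:.2f}")
print(f"sensitivity:        {100*sens:.1f}%   specificity: {100*spec:.1f}%")
```

prints:

```
mask voxels:        910
components kept:    [0] (candidates explain 59.9% variance)
pattern vs truth r: 0.989
LOOCV t-test:       t = 7.56, p = 1.61e-08
ROC cutoff:         z = 1.67
sensitivity:        88.2%   specificity: 93.8%
```

The 35% intensity mask keeps 910 brain voxels; one principal component
already captures the embedded covariance pattern (correlation 0.989 with
the ground truth), patients and controls separate strongly under LOOCV
(t = 7.6), and the ROC-optimal cutoff on the derivation z-scores
classifies the cross-validated scores at 88% sensitivity and 94%
specificity.

The same workflow is available from the shell:

```sh
ssmpca simulate --seed 1 --out-dir cohort/
ssmpca derive   --manifest cohort/manifest.csv --out-dir derived/
ssmpca validate --manifest cohort/manifest.csv --out-dir validated/
ssmpca all      --seed 1 --out-dir run/        # every stage, one JSON report
```

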