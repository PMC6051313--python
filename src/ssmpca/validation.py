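"""Leave-one-out cross-validated expression scores, ROC cutoff and accuracy.

Because small-cohort pattern derivations are prone to optimism, each
subject is scored by a pattern derived entirely without that subject: the
mask, residual profiles, PCA, component selection and the control z-score
reference are all rebuilt on the remaining n-1 subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import Mask, ScanImage, build_common_mask, compute_srp, project_score
from .pattern import derive_pattern

__all__ = [
    "LOOCVResult",
    "ROCResult",
    "loocv",
    "group_ttest",
    "roc_optimal_cutoff",
    "sens_spec",
    "REFERENCE_CUTOFF_Z",
]

#: published reference classification cutoff on the z-score scale, reported
#: for the original 17-patient / 16-control derivation of this pattern type
REFERENCE_CUTOFF_Z = 1.26


@dataclass
class LOOCVResult:
    subject_ids: list[str]
    labels: np.ndarray
    z_scores: np.ndarray
    fold_info: list[dict] = field(default_factory=list)

    @property
    def n_folds(self) -> int:
        return len(self.z_scores)


@dataclass
class ROCResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    optimal_cutoff: float
    auc: float

    @property
    def youden(self) -> np.ndarray:
        return self.sensitivity + self.specificity - 1.0


def loocv(
    scans: list[ScanImage],
    labels,
    mask_fraction: float = 0.35,
    variance_threshold: float = 0.5,
) -> LOOCVResult:
    """Leave-one-out cross-validated expression z-scores.

    For every subject the full identification procedure (common mask, SRP,
    PCA, stepwise component selection, pattern combination, control
    reference) is repeated on the other n-1 subjects, and the left-out scan
    is scored through the prospective single-scan path.  Folds that take a
    fallback path (e.g. perfect separation) are recorded in ``fold_info``,
    never dropped.

    Each fold's pattern is sign-aligned to the full-cohort pattern by dot
    product (the same convention used for bootstrap replicates) rather
    than re-oriented against the fold's own labels: under a null cohort a
    per-fold label-driven sign flip folds the group difference of the
    cross-validated scores toward positive values and inflates the type-I
    error of the subsequent t-test, while a single global orientation bit
    leaves it at its nominal level.
    """
    labels = np.asarray(labels, dtype=int)
    n = len(scans)
    if np.count_nonzero(labels == 0) < 3 or np.count_nonzero(labels == 1) < 3:
        raise ValueError("LOOCV requires at least 3 subjects per group")
    # reference pattern for fold sign alignment: the full-cohort derivation
    full_mask = build_common_mask(scans, mask_fraction)
    full_srp = compute_srp(scans, full_mask, labels)
    full_model, _ = derive_pattern(full_srp, variance_threshold)
    full_flat = np.zeros(full_mask.keep.shape)
    full_flat[full_mask.keep] = full_model.weights

    z = np.empty(n)
    fold_info = []
    for i in range(n):
        rest = [scans[j] for j in range(n) if j != i]
        rest_labels = np.delete(labels, i)
        mask = build_common_mask(rest, mask_fraction)
        srp = compute_srp(rest, mask, rest_labels)
        model, _ = derive_pattern(srp, variance_threshold)
        raw = project_score(scans[i], model.weights, mask, model.gmp)
        ref_mean, ref_sd = model.control_ref
        # a fold mask is a superset of the full mask, so the overlap is exact
        if model.weights @ full_flat[mask.keep] < 0:
            raw, ref_mean = -raw, -ref_mean
        z[i] = (raw - ref_mean) / ref_sd
        fold_info.append(
            {
                "left_out": scans[i].subject_id,
                "selected_components": model.selected_components,
                "separated": model.selection_info.get("separated", False),
                "fallback": model.selection_info.get("fallback"),
            }
        )
    return LOOCVResult(
        subject_ids=[s.subject_id for s in scans],
        labels=labels,
        z_scores=z,
        fold_info=fold_info,
    )


def group_ttest(z_scores, labels) -> tuple[float, float]:
    """Two-sample (pooled-variance) t-test of patients vs controls."""
    z = np.asarray(z_scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    a, b = z[labels == 1], z[labels == 0]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 subjects per group")
    if np.ptp(np.r_[a, b]) == 0:
        return 0.0, 1.0
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def sens_spec(z_scores, labels, cutoff: float) -> tuple[float, float]:
    """Sensitivity and specificity of the rule 'z >= cutoff => patient'."""
    z = np.asarray(z_scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pat, con = z[labels == 1], z[labels == 0]
    if len(pat) == 0 or len(con) == 0:
        raise ValueError("both classes must be present")
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    return float(np.mean(pat >= cutoff)), float(np.mean(con < cutoff))


def roc_optimal_cutoff(z_scores, labels) -> ROCResult:
    """ROC sweep over all candidate cutoffs; optimum by Youden's J.

    Candidates are the midpoints between adjacent sorted unique scores,
    plus one cutoff below the minimum and one above the maximum (so
    'everyone positive' and 'no one positive' are both swept).  Ties in
    J = sensitivity + specificity - 1 are broken toward higher specificity,
    then toward the lower cutoff value.  AUC is the rank-based area
    (equal to the Mann-Whitney U statistic over n1*n2).
    """
    z = np.asarray(z_scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    uniq = np.unique(z)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    thresholds = np.r_[uniq[0] - 1.0, mids, uniq[-1] + 1.0]
    sens = np.array([np.mean(z[labels == 1] >= t) for t in thresholds])
    spec = np.array([np.mean(z[labels == 0] < t) for t in thresholds])
    j = sens + spec - 1.0
    order = sorted(range(len(thresholds)), key=lambda i: (-j[i], -spec[i], thresholds[i]))
    best = order[0]
    # rank-based AUC (midranks handle ties)
    ranks = stats.rankdata(z)
    n1 = int(np.count_nonzero(labels == 1))
    n0 = len(z) - n1
    u = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0
    return ROCResult(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        optimal_cutoff=float(thresholds[best]),
        auc=float(u / (n1 * n0)),
    )
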