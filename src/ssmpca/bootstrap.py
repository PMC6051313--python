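"""Bootstrap stability of the voxel weights of a derived pattern.

The entire identification procedure (mask, residual profiles, PCA,
stepwise logistic selection, combination) is repeated on cohorts resampled
with replacement within each group, giving a distribution of weights per
voxel.  Voxels whose one-sided percentile interval excludes zero are
declared stable; the displayed value at a stable voxel is the replicate
median.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Mask, ScanImage, build_common_mask, scan_threshold_mask, srp_from_logs, SRPMatrix
from .pattern import derive_pattern

__all__ = [
    "BootstrapResult",
    "bootstrap_patterns",
    "threshold_stable_voxels",
    "DEFAULT_N_REPS",
    "DEFAULT_ONE_SIDED_LEVEL",
]

DEFAULT_N_REPS = 1000
DEFAULT_ONE_SIDED_LEVEL = 0.95


@dataclass
class BootstrapResult:
    n_reps: int
    n_redrawn: int
    mask: Mask
    pct_low: np.ndarray
    median: np.ndarray
    pct_high: np.ndarray
    stable_mask: np.ndarray  # boolean over masked voxels
    stable_values: np.ndarray  # median where stable, 0 elsewhere
    one_sided_level: float

    def stable_volume(self) -> np.ndarray:
        vol = np.zeros(self.mask.keep.shape)
        vol[self.mask.keep] = self.stable_values
        return vol

    def counts(self) -> dict:
        pos = int(np.count_nonzero(self.stable_mask & (self.median > 0)))
        neg = int(np.count_nonzero(self.stable_mask & (self.median < 0)))
        return {"stable_total": pos + neg, "stable_positive": pos, "stable_negative": neg}


def bootstrap_patterns(
    scans: list[ScanImage],
    labels,
    n_reps: int = DEFAULT_N_REPS,
    seed: int = 0,
    mask_fraction: float = 0.35,
    variance_threshold: float = 0.5,
) -> tuple[np.ndarray, Mask, np.ndarray, int]:
    """Replicate voxel-weight distributions from within-group resampling.

    Each replicate draws subjects with replacement separately within the
    control and patient groups (group sizes preserved), reruns the full
    derivation, and sign-aligns the replicate pattern to the original
    full-cohort pattern (flipping it when their dot product is negative).
    Replicate weights are recorded at the voxels of the original analysis
    mask; a resampled cohort's own mask always contains those voxels
    because it intersects per-scan masks of a subject subset.  Failing
    replicates are redrawn (counted); more than 20% failures aborts.

    Returns ``(weights[n_reps, n_voxels], mask, original_weights, n_redrawn)``.
    """
    labels = np.asarray(labels, dtype=int)
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if np.count_nonzero(labels == 0) < 3 or np.count_nonzero(labels == 1) < 3:
        raise ValueError("need at least 3 subjects per group")
    rng = np.random.default_rng(seed)

    mask = build_common_mask(scans, mask_fraction)
    flat0 = mask.flat

    # hoist per-scan thresholds and logs out of the replicate loop;
    # background voxels may be non-positive, so log only where positive
    shape = scans[0].shape
    per_scan = np.stack([scan_threshold_mask(s, mask_fraction).ravel() for s in scans])
    logs = np.stack([
        np.where(s.voxels.ravel() > 0, np.log(np.where(s.voxels.ravel() > 0, s.voxels.ravel(), 1.0)), -np.inf)
        for s in scans
    ])
    ids = [s.subject_id for s in scans]

    def derive_indices(idx: np.ndarray):
        sub_mask = per_scan[idx].all(axis=0)
        srp_vals, gmp = srp_from_logs(logs[np.ix_(idx, np.nonzero(sub_mask)[0])])
        srp = SRPMatrix(
            values=srp_vals,
            subject_ids=[ids[i] for i in idx],
            group_labels=labels[idx],
            mask=Mask(sub_mask.reshape(shape)),
            group_mean_profile=gmp,
        )
        model, _ = derive_pattern(srp, variance_threshold)
        # restrict to the original analysis mask voxels
        keep_in_sub = flat0[sub_mask]
        return model.weights[keep_in_sub]

    orig_weights = derive_indices(np.arange(len(scans)))

    idx_c = np.nonzero(labels == 0)[0]
    idx_p = np.nonzero(labels == 1)[0]
    weights = np.empty((n_reps, mask.n_voxels))
    n_redrawn = 0
    for r in range(n_reps):
        while True:
            draw = np.r_[rng.choice(idx_c, len(idx_c), replace=True),
                         rng.choice(idx_p, len(idx_p), replace=True)]
            try:
                w = derive_indices(draw)
            except (ValueError, np.linalg.LinAlgError):
                n_redrawn += 1
                if n_redrawn > 0.2 * n_reps:
                    raise RuntimeError(
                        f"more than 20% of bootstrap replicates failed "
                        f"({n_redrawn} redraws in {r + 1} replicates)"
                    )
                continue
            break
        if w @ orig_weights < 0:
            w = -w
        weights[r] = w
    return weights, mask, orig_weights, n_redrawn


def threshold_stable_voxels(
    weights: np.ndarray,
    mask: Mask,
    one_sided_level: float = DEFAULT_ONE_SIDED_LEVEL,
    n_redrawn: int = 0,
) -> BootstrapResult:
    """Stable-voxel map from replicate weight distributions.

    A voxel is stable-positive when its lower (1-level) percentile exceeds
    zero, stable-negative when its upper (level) percentile is below zero;
    intervals straddling zero mark the voxel non-informative.  Percentiles
    use the linear-interpolation empirical convention.
    """
    weights = np.asarray(weights, dtype=float)
    if weights.ndim != 2 or weights.shape[0] < 1:
        raise ValueError("weights must be (n_reps, n_voxels), non-empty")
    if not 0.5 < one_sided_level < 1:
        raise ValueError("one_sided_level must lie in (0.5, 1)")
    lo = np.percentile(weights, 100.0 * (1 - one_sided_level), axis=0)
    hi = np.percentile(weights, 100.0 * one_sided_level, axis=0)
    med = np.percentile(weights, 50.0, axis=0)
    stable = (lo > 0) | (hi < 0)
    return BootstrapResult(
        n_reps=weights.shape[0],
        n_redrawn=n_redrawn,
        mask=mask,
        pct_low=lo,
        median=med,
        pct_high=hi,
        stable_mask=stable,
        stable_values=np.where(stable, med, 0.0),
        one_sided_level=one_sided_level,
    )
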