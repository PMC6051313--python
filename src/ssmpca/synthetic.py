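"""Synthetic co-registered cohorts with a known embedded covariance pattern.

The generative model mirrors what the scaled-subprofile-model double
centering removes: each subject's log intensity at voxel v is

    log I_sv = alpha_s + mu_v + z_s * P_v + eps_sv

with a per-subject global offset ``alpha_s`` (scanner/dose scaling), a
shared mean profile ``mu_v``, a ground-truth spatial pattern ``P_v``
(zero-mean, unit-norm over the brain support) scaled by a per-subject
expression score ``z_s`` (higher on average in patients), and i.i.d. voxel
noise.  Outside an ellipsoidal brain support the intensity is a small
positive background so the intensity-threshold mask has something to
exclude.  Matching clinical covariates (ataxia severity, CAG repeats,
onset, neuropsychology) are generated with realistic correlation
structure against the true expression scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .core import ScanImage

__all__ = [
    "CohortParams",
    "GroundTruth",
    "make_brain_support",
    "make_ground_truth_pattern",
    "simulate_cohort",
    "simulate_clinical",
    "make_roi_masks",
    "simulate_roi_dataset",
]

#: 8 ataxia rating sub-items (gait..heel-shin); totals are their sum.
SARA_ITEMS = (
    "gait",
    "stance",
    "sitting",
    "speech",
    "finger_chase",
    "nose_finger",
    "fast_alternating_hand",
    "heel_shin",
)

#: relative weight of each sub-item in the severity total; gait and stance
#: dominate, matching the clinical picture in cerebellar ataxia.
_SARA_ITEM_WEIGHTS = np.array([0.28, 0.22, 0.08, 0.12, 0.08, 0.08, 0.07, 0.07])

NEUROPSYCH_COLUMNS = (
    "semantic_fluency",
    "letter_fluency",
    "ravlt_immediate",
    "ravlt_delayed",
    "sdmt",
)


@dataclass(frozen=True)
class CohortParams:
    """Study-condition parameters of the synthetic cohort.

    Defaults emulate the target study design: 16 controls + 17 patients,
    a between-group expression separation of 3 within-group SDs, 5% voxel
    noise on the log scale and 10% inter-subject global scaling spread.
    """

    n_controls: int = 16
    n_patients: int = 17
    grid_dims: tuple[int, int, int] = (20, 20, 20)
    effect_size: float = 3.0
    score_sd: float = 1.0
    noise_sd: float = 0.05
    global_scale_sd: float = 0.1
    smoothing_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_controls < 2 or self.n_patients < 2:
            raise ValueError("need at least 2 subjects per group")
        if len(self.grid_dims) != 3 or any(d < 8 for d in self.grid_dims):
            raise ValueError("grid_dims must be 3 integers, each >= 8")
        for name in ("score_sd", "noise_sd", "global_scale_sd", "smoothing_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def with_(self, **kw) -> "CohortParams":
        return replace(self, **kw)


@dataclass
class GroundTruth:
    """The embedded pattern and per-subject scores a cohort was built from."""

    pattern: np.ndarray  # 3D, zero outside brain_support, mean 0 / norm 1 on it
    true_scores: np.ndarray
    brain_support: np.ndarray
    global_offsets: np.ndarray = field(default_factory=lambda: np.empty(0))

    def cluster_mask(self, rel_height: float = 0.5) -> np.ndarray:
        """Voxels belonging to the pattern's clusters (|P| >= rel_height * max|P|)."""
        return np.abs(self.pattern) >= rel_height * np.abs(self.pattern).max()

    def null_mask(self) -> np.ndarray:
        """Support voxels with exactly zero pattern signal."""
        return self.brain_support & (self.pattern == 0)


def make_brain_support(grid_dims) -> np.ndarray:
    """Ellipsoidal brain support at 60% of the grid extent."""
    nx, ny, nz = grid_dims
    ix, iy, iz = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    cx, cy, cz = (nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2
    ax, ay, az = 0.6 * nx / 2, 0.6 * ny / 2, 0.6 * nz / 2
    return ((ix - cx) / ax) ** 2 + ((iy - cy) / ay) ** 2 + ((iz - cz) / az) ** 2 <= 1.0


# fractional blob centers (relative to grid), amplitude signs balanced so
# the support mean is already near zero before exact centering
_BLOB_SPEC = [
    ((0.42, 0.38, 0.36), +1.0),
    ((0.60, 0.62, 0.60), +1.0),
    ((0.38, 0.62, 0.55), -1.0),
    ((0.62, 0.40, 0.45), -1.0),
]


def make_ground_truth_pattern(
    grid_dims, smoothing_sigma: float = 1.0, seed: int = 0
) -> GroundTruth:
    """Smooth spatial field with positive and negative clusters in the support.

    Four Gaussian blobs (two of each sign) are placed at jittered canonical
    locations and optionally smoothed further.  Voxels below 5% of the peak
    magnitude are set exactly to zero so the pattern has a well-defined
    null region (true weight 0) outside its clusters; the remaining voxels
    are mean-balanced so the pattern sums to zero over the support, then
    the whole field is scaled to unit Euclidean norm.  Deterministic in
    ``seed``.
    """
    grid_dims = tuple(int(d) for d in grid_dims)
    if len(grid_dims) != 3 or any(d < 8 for d in grid_dims):
        raise ValueError("grid_dims must be 3 integers, each >= 8")
    rng = np.random.default_rng(seed)
    support = make_brain_support(grid_dims)
    field_ = np.zeros(grid_dims)
    base_width = 1.8
    for (fx, fy, fz), amp in _BLOB_SPEC:
        jitter = rng.uniform(-0.05, 0.05, size=3)
        center = tuple(
            int(round((f + j) * (d - 1))) for f, j, d in zip((fx, fy, fz), jitter, grid_dims)
        )
        field_[center] += amp
    field_ = gaussian_filter(field_, base_width)
    if smoothing_sigma > 0:
        field_ = gaussian_filter(field_, smoothing_sigma)
    field_[~support] = 0.0
    keep = np.abs(field_) > 0.05 * np.abs(field_).max()
    field_[~keep] = 0.0
    field_[keep] -= field_[keep].mean()
    field_ /= np.linalg.norm(field_)
    return GroundTruth(pattern=field_, true_scores=np.empty(0), brain_support=support)


def simulate_cohort(
    params: CohortParams,
) -> tuple[list[ScanImage], GroundTruth, pd.DataFrame]:
    """Generate one cohort of co-registered intensity images.

    Returns the scans (controls first, then patients), the ground truth
    (pattern, true expression scores, support, global offsets) and a
    subject table with ids, group labels and the latent per-subject
    variables.  Background outside the support is 1% of the in-brain mean
    intensity (scaled by each subject's global offset so that global
    rescaling acts on the whole image).
    """
    rng = np.random.default_rng(params.seed)
    truth = make_ground_truth_pattern(params.grid_dims, params.smoothing_sigma, params.seed)
    support = truth.brain_support
    n_sup = int(support.sum())

    # shared mean profile: smooth mild variation around log(100)
    mu = gaussian_filter(rng.normal(0.0, 1.0, params.grid_dims), 2.0)
    mu = np.log(100.0) + 0.1 * mu / max(mu[support].std(), 1e-12)

    n = params.n_controls + params.n_patients
    labels = np.r_[np.zeros(params.n_controls, int), np.ones(params.n_patients, int)]
    z = rng.normal(0.0, params.score_sd, n) + params.effect_size * labels
    alpha = rng.normal(0.0, params.global_scale_sd, n)

    background = 0.01 * float(np.exp(mu[support]).mean())
    scans = []
    for s in range(n):
        eps = rng.normal(0.0, params.noise_sd, n_sup)
        vol = np.full(params.grid_dims, background)
        vol[support] = np.exp(mu[support] + z[s] * truth.pattern[support] + eps)
        vol *= np.exp(alpha[s])
        gid = "C" if labels[s] == 0 else "P"
        idx = s if labels[s] == 0 else s - params.n_controls
        scans.append(ScanImage(subject_id=f"{gid}{idx:02d}", voxels=vol))

    truth.true_scores = z
    truth.global_offsets = alpha
    table = pd.DataFrame(
        {
            "subject_id": [sc.subject_id for sc in scans],
            "group": np.where(labels == 0, "control", "patient"),
            "label": labels,
            "true_score": z,
            "global_offset": alpha,
        }
    )
    return scans, truth, table


def _softplus(x):
    return np.logaddexp(0.0, x)


def _round_half(x):
    return np.round(np.asarray(x) * 2.0) / 2.0


def simulate_clinical(
    true_scores,
    group_labels,
    seed: int = 0,
    noise_scale: float = 1.0,
) -> pd.DataFrame:
    """Clinical covariates consistent with the true expression scores.

    Patients' ataxia severity (SARA total, 0-40 scale in 0.5 steps) is a
    strictly increasing softplus map of the true score plus noise; controls
    sit at or near 0.  CAG repeat length (patients only) is negatively
    coupled to age at onset; letter fluency declines with expression while
    the remaining neuropsychological scores carry mostly group-level
    differences.  With ``noise_scale=0`` the SARA map is exactly monotone
    in the true score (no rounding ties are introduced).
    """
    z = np.asarray(true_scores, dtype=float)
    labels = np.asarray(group_labels, dtype=int)
    if z.shape != labels.shape:
        raise ValueError("one score per subject required")
    rng = np.random.default_rng(seed)
    n = len(z)
    pat = labels == 1

    sara = np.where(
        pat,
        3.2 * _softplus(z) + noise_scale * 2.5 * rng.normal(size=n),
        np.maximum(0.0, noise_scale * 0.6 * rng.normal(size=n)),
    )
    sara = np.maximum(sara, 0.0)
    if noise_scale > 0:
        sara = _round_half(sara)

    # split the total into 8 sub-items; gait/stance carry most severity
    props = _SARA_ITEM_WEIGHTS[None, :] * np.exp(
        noise_scale * 0.25 * rng.normal(size=(n, len(SARA_ITEMS)))
    )
    props /= props.sum(axis=1, keepdims=True)
    items = sara[:, None] * props
    if noise_scale > 0:
        items = _round_half(items)

    cag = np.where(pat, np.round(69 + 3.5 * rng.normal(size=n)), np.nan)
    onset = np.where(
        pat, 35.6 - 1.8 * (cag - 69) + noise_scale * 5.0 * rng.normal(size=n), np.nan
    )
    onset = np.clip(onset, 18.0, 60.0)
    duration = np.where(
        pat, np.clip(9.7 + noise_scale * 7.0 * rng.normal(size=n), 1.0, 35.0), np.nan
    )
    age = np.where(
        pat,
        onset + duration,
        np.clip(49.4 + 13.5 * rng.normal(size=n), 20.0, 65.0),
    )
    sex = rng.integers(0, 2, n)
    education = np.clip(np.round(5.4 + 0.8 * rng.normal(size=n)), 3, 7)

    zc = z - z[pat].mean() if pat.any() else z
    neuro = {
        "semantic_fluency": 26.2 - 6.0 * labels - 1.0 * zc + noise_scale * 6.5 * rng.normal(size=n),
        "letter_fluency": 38.6 - 7.0 * labels - 4.0 * zc + noise_scale * 6.0 * rng.normal(size=n),
        "ravlt_immediate": 50.7 - 8.0 * labels - 1.0 * zc + noise_scale * 8.0 * rng.normal(size=n),
        "ravlt_delayed": 11.4 - 2.5 * labels - 0.3 * zc + noise_scale * 2.5 * rng.normal(size=n),
        "sdmt": 62.5 - 18.0 * labels - 1.5 * zc + noise_scale * 8.0 * rng.normal(size=n),
    }
    hads_anx = np.clip(4.0 - 0.5 * labels + noise_scale * 2.5 * rng.normal(size=n), 0, 21)
    hads_dep = np.clip(1.6 + 3.7 * labels + 0.2 * zc + noise_scale * 2.0 * rng.normal(size=n), 0, 21)

    table = pd.DataFrame(
        {
            "subject_id": [
                f"{'C' if l == 0 else 'P'}{i:02d}"
                for i, l in zip(_subject_index(labels), labels)
            ],
            "group": np.where(pat, "patient", "control"),
            "label": labels,
            "sex": np.where(sex == 1, "M", "F"),
            "age": np.round(age, 1),
            "age_at_onset": np.round(onset, 1),
            "disease_duration": np.round(duration, 1),
            "cag_repeats": cag,
            "education": education,
            "sara_total": sara,
            **{f"sara_{item}": items[:, i] for i, item in enumerate(SARA_ITEMS)},
            "hads_anxiety": np.round(hads_anx, 1),
            "hads_depression": np.round(hads_dep, 1),
            **{k: np.round(v, 1) for k, v in neuro.items()},
        }
    )
    return table


def _subject_index(labels: np.ndarray) -> np.ndarray:
    """Within-group running index so ids match simulate_cohort's."""
    idx = np.zeros(len(labels), dtype=int)
    counts = {0: 0, 1: 0}
    for i, l in enumerate(labels):
        idx[i] = counts[int(l)]
        counts[int(l)] += 1
    return idx


# ---------------------------------------------------------------------------
# ROI stage inputs: geometric ROI masks, grey-matter maps, uptake images
# ---------------------------------------------------------------------------

# fractional (center, semi-axes) boxes for each ROI; lateralized pairs share
# a pairing key and mirror in x
_ROI_GEOMETRY = {
    "brainstem": ((0.50, 0.45, 0.30), (0.06, 0.06, 0.10), None),
    "cerebellar_vermis": ((0.50, 0.32, 0.38), (0.05, 0.05, 0.06), None),
    "cerebellum_left": ((0.36, 0.32, 0.40), (0.08, 0.07, 0.08), "cerebellum"),
    "cerebellum_right": ((0.64, 0.32, 0.40), (0.08, 0.07, 0.08), "cerebellum"),
    "caudate_left": ((0.40, 0.55, 0.55), (0.05, 0.05, 0.06), "caudate"),
    "caudate_right": ((0.60, 0.55, 0.55), (0.05, 0.05, 0.06), "caudate"),
    "superior_frontal_left": ((0.40, 0.68, 0.62), (0.07, 0.06, 0.07), "superior_frontal"),
    "superior_frontal_right": ((0.60, 0.68, 0.62), (0.07, 0.06, 0.07), "superior_frontal"),
}


def make_roi_masks(grid_dims) -> list:
    """Geometric ROI definitions (ellipsoids) inside the brain support."""
    from .roi import ROIDefinition  # local import to avoid a cycle

    nx, ny, nz = grid_dims
    support = make_brain_support(grid_dims)
    ix, iy, iz = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    rois = []
    for name, ((fx, fy, fz), (ax, ay, az), pair) in _ROI_GEOMETRY.items():
        cx, cy, cz = fx * (nx - 1), fy * (ny - 1), fz * (nz - 1)
        rx, ry, rz = max(ax * nx, 1.0), max(ay * ny, 1.0), max(az * nz, 1.0)
        mask = (((ix - cx) / rx) ** 2 + ((iy - cy) / ry) ** 2 + ((iz - cz) / rz) ** 2 <= 1.0)
        mask &= support
        lat = "left" if name.endswith("_left") else "right" if name.endswith("_right") else "midline"
        rois.append(ROIDefinition(name=name, mask=mask, laterality=lat, pair_key=pair))
    return rois


def simulate_roi_dataset(
    n_subjects: int = 17,
    grid_dims=(20, 20, 20),
    seed: int = 0,
    coupling: float = 0.12,
    regional_noise_sd: float = 0.05,
    coupled_roi: str = "cerebellar_vermis",
):
    """Uptake images + grey-matter maps with atrophy-metabolism coupling in one ROI.

    Each subject carries a latent severity; in the coupled ROI both the
    grey-matter density and the uptake decline with severity (shared
    factor => correlated across subjects), while the other ROIs' uptake
    fluctuates independently.  Grey-matter variation is modeled only in
    the cerebellar structures (the coupled ROI and the cerebellar
    hemispheres, the latter without matching uptake change, providing a
    proper null for the atrophy-metabolism test); elsewhere grey matter is
    constant across subjects.  A clinical table with severity-linked
    ataxia scores and disease duration is returned alongside.

    Returns ``(fdg_scans, gm_maps, rois, clinical, severity)``.
    """
    rng = np.random.default_rng(seed)
    support = make_brain_support(grid_dims)
    rois = make_roi_masks(grid_dims)
    severity = rng.normal(0.0, 1.0, n_subjects)

    fdg_scans, gm_maps = [], []
    for s in range(n_subjects):
        fdg = np.zeros(grid_dims)
        fdg[support] = 100.0 * np.exp(rng.normal(0.0, 0.02, int(support.sum())))
        gm = np.where(support, 0.5, 0.0)
        for roi in rois:
            if roi.name == coupled_roi:
                gm_mult = 1.0 - coupling * severity[s] + regional_noise_sd * rng.normal()
                fdg_mult = 1.0 - coupling * severity[s] + regional_noise_sd * rng.normal()
            elif roi.pair_key == "cerebellum":
                gm_mult = 1.0 - coupling * severity[s] + regional_noise_sd * rng.normal()
                fdg_mult = 1.0 + regional_noise_sd * rng.normal()
            else:
                gm_mult = 1.0  # no atrophy variability outside the cerebellum
                fdg_mult = 1.0 + regional_noise_sd * rng.normal()
            gm[roi.mask] *= np.clip(gm_mult, 0.05, None)
            fdg[roi.mask] *= np.clip(fdg_mult, 0.05, None)
        fdg_scans.append(ScanImage(subject_id=f"P{s:02d}", voxels=fdg))
        gm_maps.append(gm)

    clinical = pd.DataFrame(
        {
            "subject_id": [f"P{s:02d}" for s in range(n_subjects)],
            "sara_total": np.maximum(0.0, 8.0 + 3.0 * severity + 1.5 * rng.normal(size=n_subjects)),
            "disease_duration": np.clip(10.0 + 2.0 * severity + 3.0 * rng.normal(size=n_subjects), 1.0, 35.0),
        }
    )
    return fdg_scans, gm_maps, rois, clinical, severity
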