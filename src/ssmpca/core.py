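"""Scaled subprofile model (SSM) core: masking, log double-centering, PCA, projection.

The SSM removes per-subject global scaling and the cohort's shared spatial
profile from log-transformed images, leaving a Subject Residual Profile (SRP)
per subject.  PCA of the SRP matrix yields spatial covariance patterns; the
projection of a residual profile onto a pattern is that subject's expression
score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ScanImage",
    "Mask",
    "SRPMatrix",
    "PCAResult",
    "build_common_mask",
    "scan_threshold_mask",
    "compute_srp",
    "srp_from_logs",
    "run_pca",
    "select_top_variance",
    "project_score",
]

DEFAULT_MASK_FRACTION = 0.35


@dataclass
class ScanImage:
    """One subject's co-registered 3D intensity image.

    Parameters
    ----------
    subject_id : str
        Unique identifier.
    voxels : ndarray, shape (nx, ny, nz)
        Non-negative intensities (e.g. FDG uptake).
    affine : ndarray, shape (4, 4)
        Voxel-to-world transform (RAS+).
    """

    subject_id: str
    voxels: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3:
            raise ValueError(f"scan {self.subject_id!r}: voxels must be 3D")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError(f"scan {self.subject_id!r}: non-finite voxel values")
        if not np.any(self.voxels > 0):
            raise ValueError(f"scan {self.subject_id!r}: no positive voxels")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.voxels.shape


@dataclass
class Mask:
    """Boolean analysis mask shared by all subjects."""

    keep: np.ndarray

    def __post_init__(self) -> None:
        self.keep = np.asarray(self.keep, dtype=bool)
        if self.n_voxels == 0:
            raise ValueError("mask has no voxels")

    @property
    def n_voxels(self) -> int:
        return int(self.keep.sum())

    @property
    def flat(self) -> np.ndarray:
        return self.keep.ravel()


@dataclass
class SRPMatrix:
    """Subjects x masked-voxels matrix of doubly-centered log intensities.

    ``values[s, v]`` is subject ``s``'s log intensity at masked voxel ``v``
    after removal of the subject's own mean (global scaling) and the group
    mean profile (GMP).  Row sums and column sums are both ~0 by
    construction.
    """

    values: np.ndarray
    subject_ids: list[str]
    group_labels: np.ndarray
    mask: Mask
    group_mean_profile: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.group_labels = np.asarray(self.group_labels, dtype=int)
        n, v = self.values.shape
        if len(self.subject_ids) != n or self.group_labels.shape != (n,):
            raise ValueError("subject metadata does not match matrix rows")
        if self.group_mean_profile.shape != (v,):
            raise ValueError("GMP length does not match matrix columns")


@dataclass
class PCAResult:
    """Voxel-space principal components of an SRP matrix.

    ``components`` holds unit-norm eigenvector maps (rows, masked-voxel
    space), ordered by decreasing variance accounted for (``vaf``).
    ``subject_loadings[s, k]`` is subject ``s``'s score on component ``k``,
    so that ``loadings @ components`` reconstructs the SRP matrix.
    """

    components: np.ndarray
    subject_loadings: np.ndarray
    vaf: np.ndarray


def scan_threshold_mask(scan: ScanImage, fraction: float) -> np.ndarray:
    """Per-scan mask: voxels at or above ``fraction`` of the scan's maximum."""
    return scan.voxels >= fraction * scan.voxels.max()


def build_common_mask(scans: list[ScanImage], fraction: float = DEFAULT_MASK_FRACTION) -> Mask:
    """Intersect per-scan intensity-threshold masks into one common mask.

    Each scan keeps voxels >= ``fraction`` x its own whole-image maximum;
    the per-scan masks are combined multiplicatively (voxelwise AND) so the
    result contains only voxels supported in every subject.
    """
    if len(scans) < 2:
        raise ValueError("need at least 2 scans to build a common mask")
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    shape = scans[0].shape
    for s in scans:
        if s.shape != shape:
            raise ValueError(f"scan {s.subject_id!r} has shape {s.shape}, expected {shape}")
    keep = np.ones(shape, dtype=bool)
    for s in scans:
        keep &= scan_threshold_mask(s, fraction)
    if not keep.any():
        raise ValueError(f"common mask is empty at threshold fraction {fraction}")
    return Mask(keep)


def compute_srp(scans: list[ScanImage], mask: Mask, group_labels=None) -> SRPMatrix:
    """Log-transform masked intensities and remove subject and group means.

    The double centering is: row-center each subject's log profile
    (removing global scaling), then subtract the across-subject mean of the
    row-centered data (the group mean profile, GMP).  Both row and column
    sums of the result are zero to machine precision.
    """
    if group_labels is None:
        group_labels = np.zeros(len(scans), dtype=int)
    flat_mask = mask.flat
    logs = np.empty((len(scans), mask.n_voxels))
    for i, s in enumerate(scans):
        vals = s.voxels.ravel()[flat_mask]
        n_bad = int(np.count_nonzero(vals <= 0))
        if n_bad:
            raise ValueError(
                f"scan {s.subject_id!r}: {n_bad} masked voxel(s) are non-positive; "
                "cannot log-transform"
            )
        logs[i] = np.log(vals)
    row_centered = logs - logs.mean(axis=1, keepdims=True)
    gmp = row_centered.mean(axis=0)
    srp = row_centered - gmp
    return SRPMatrix(
        values=srp,
        subject_ids=[s.subject_id for s in scans],
        group_labels=np.asarray(group_labels, dtype=int),
        mask=mask,
        group_mean_profile=gmp,
    )


def srp_from_logs(log_rows: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Double-center precomputed log rows; return (SRP, GMP).

    Fast path used by resampling loops where the log transform is hoisted
    out of the loop.
    """
    rc = log_rows - log_rows.mean(axis=1, keepdims=True)
    gmp = rc.mean(axis=0)
    return rc - gmp, gmp


def run_pca(srp: SRPMatrix | np.ndarray, align_labels=None) -> PCAResult:
    """Principal component analysis of the SRP matrix in voxel space.

    Computed through the singular value decomposition of the SRP matrix,
    which is numerically equivalent to eigendecomposition of the voxel-space
    covariance but stable and cheap (the rank is at most n_subjects - 1
    because of the double centering).  ``vaf`` is each squared singular
    value over the total sum of squares.

    Component signs are arbitrary; if ``align_labels`` (binary, 1 = patient)
    is given, each component is flipped so its subject loadings correlate
    non-negatively with the labels, otherwise the largest-magnitude voxel
    weight is made positive.
    """
    values = srp.values if isinstance(srp, SRPMatrix) else np.asarray(srp, dtype=float)
    if values.shape[0] < 3:
        raise ValueError("PCA requires at least 3 subjects")
    total_ss = np.sum(values**2)
    if total_ss == 0:
        raise ValueError("SRP matrix is identically zero; PCA undefined")
    u, s, vt = np.linalg.svd(values, full_matrices=False)
    keep = s > s[0] * 1e-12
    u, s, vt = u[:, keep], s[keep], vt[keep]
    loadings = u * s
    vaf = s**2 / total_ss
    if align_labels is not None:
        y = np.asarray(align_labels, dtype=float)
        yc = y - y.mean()
        flip = (loadings * yc[:, None]).sum(axis=0) < 0
    else:
        peak = np.abs(vt).argmax(axis=1)
        flip = vt[np.arange(vt.shape[0]), peak] < 0
    sign = np.where(flip, -1.0, 1.0)
    return PCAResult(components=vt * sign[:, None], subject_loadings=loadings * sign, vaf=vaf)


def select_top_variance(pca: PCAResult, threshold: float = 0.5) -> list[int]:
    """Indices (0-based) of the smallest component prefix whose cumulative
    variance accounted for reaches ``threshold``.

    The component that first reaches the threshold is included; if the total
    falls short of the threshold all components are returned.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    cum = np.cumsum(pca.vaf)
    reached = np.nonzero(cum >= threshold - 1e-12)[0]
    last = reached[0] if reached.size else len(pca.vaf) - 1
    return list(range(last + 1))


def project_score(
    scan: ScanImage | np.ndarray,
    pattern_voxels: np.ndarray,
    mask: Mask,
    gmp: np.ndarray,
) -> float:
    """Expression score of one scan on a fixed pattern.

    The scan is masked, log-transformed, centered by its own masked mean and
    by the stored derivation GMP, and the residual is projected (dot
    product) onto the pattern weights.  For a subject that was part of the
    derivation this reproduces the SRP-row projection exactly.
    """
    pattern_voxels = np.asarray(pattern_voxels, dtype=float)
    if pattern_voxels.shape != (mask.n_voxels,):
        raise ValueError("pattern is not defined on the given mask")
    voxels = scan.voxels if isinstance(scan, ScanImage) else np.asarray(scan, dtype=float)
    if voxels.shape != mask.keep.shape:
        raise ValueError(
            f"scan shape {voxels.shape} does not match mask shape {mask.keep.shape}"
        )
    vals = voxels.ravel()[mask.flat]
    if np.any(vals <= 0):
        raise ValueError("scan has non-positive intensities inside the mask")
    log_vals = np.log(vals)
    resid = log_vals - log_vals.mean() - gmp
    return float(resid @ pattern_voxels)
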