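"""Region-of-interest metabolism vs grey-matter analysis.

Summarizes per-subject regional uptake (normalized to the whole-brain
total) and grey-matter volume, merges lateralized region pairs by
summation, and correlates the two measures — and clinical severity /
disease duration — region by region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import ScanImage

__all__ = [
    "ROIDefinition",
    "summarize_rois",
    "roi_correlations",
    "DEFAULT_ALPHA_ROI",
]

DEFAULT_ALPHA_ROI = 0.05  # exploratory stage: uncorrected, flagged as such


@dataclass
class ROIDefinition:
    """Named boolean region mask; lateralized pairs share ``pair_key``."""

    name: str
    mask: np.ndarray
    laterality: str = "midline"  # left / right / midline
    pair_key: str | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError(f"ROI {self.name!r} has an empty mask")

    @property
    def merged_name(self) -> str:
        return self.pair_key if self.pair_key else self.name


def summarize_rois(
    fdg_scans: list[ScanImage],
    gm_maps: list[np.ndarray],
    rois: list[ROIDefinition],
    brain_mask: np.ndarray | None = None,
    voxel_volume: float = 1.0,
) -> pd.DataFrame:
    """Per-subject, per-region uptake fraction and grey-matter volume.

    Uptake in a region is its voxel sum divided by the subject's
    whole-brain sum (over ``brain_mask``, default: voxels positive in the
    subject's own scan), making it invariant to global intensity scaling.
    Grey-matter volume is the sum of density values times ``voxel_volume``.
    Lateralized pairs are merged by summation before any statistics.

    Returns a tidy frame: subject_id, roi, uptake, gm_volume.
    """
    if len(fdg_scans) != len(gm_maps):
        raise ValueError("need one grey-matter map per scan")
    shape = fdg_scans[0].shape
    for roi in rois:
        if roi.mask.shape != shape:
            raise ValueError(f"ROI {roi.name!r} shape {roi.mask.shape} != scan shape {shape}")
        if brain_mask is not None and not (roi.mask & brain_mask).any():
            raise ValueError(f"ROI {roi.name!r} lies entirely outside the brain mask")
    merged: dict[str, list[ROIDefinition]] = {}
    for roi in rois:
        merged.setdefault(roi.merged_name, []).append(roi)

    rows = []
    for scan, gm in zip(fdg_scans, gm_maps):
        gm = np.asarray(gm, dtype=float)
        if gm.shape != shape:
            raise ValueError(f"grey-matter map shape {gm.shape} != scan shape {shape}")
        brain = brain_mask if brain_mask is not None else scan.voxels > 0
        total = float(scan.voxels[brain].sum())
        if total <= 0:
            raise ValueError(f"scan {scan.subject_id!r}: non-positive whole-brain uptake")
        for name, parts in merged.items():
            uptake = sum(float(scan.voxels[p.mask].sum()) for p in parts) / total
            vol = sum(float(gm[p.mask].sum()) for p in parts) * voxel_volume
            rows.append({"subject_id": scan.subject_id, "roi": name,
                         "uptake": uptake, "gm_volume": vol})
    return pd.DataFrame(rows)


def roi_correlations(
    summary: pd.DataFrame,
    clinical: pd.DataFrame | None = None,
    alpha: float = DEFAULT_ALPHA_ROI,
) -> pd.DataFrame:
    """Region-wise correlations between atrophy, metabolism and clinical state.

    Per merged region: Pearson r between grey-matter volume and normalized
    uptake across subjects; if a clinical table (``sara_total``,
    ``disease_duration``) is given, Spearman rho of each against both
    measures.  Significance is at ``alpha``, uncorrected for multiple
    regions (flagged as such in the output).  Constant columns are skipped
    with a reason.
    """
    if len(summary) < 3:
        raise ValueError("need at least 3 subjects")
    rows = []
    clin = clinical.set_index("subject_id") if clinical is not None else None
    for roi, sub in summary.groupby("roi", sort=True):
        pairs = [("gm_volume", "uptake", "pearson")]
        if clin is not None:
            for cvar in ("sara_total", "disease_duration"):
                if cvar in clin:
                    pairs += [(cvar, "gm_volume", "spearman"), (cvar, "uptake", "spearman")]
        for xvar, yvar, method in pairs:
            if xvar in sub.columns:
                x = sub[xvar].to_numpy(dtype=float)
            else:
                x = clin.loc[sub["subject_id"], xvar].to_numpy(dtype=float)
            y = sub[yvar].to_numpy(dtype=float)
            ok = np.isfinite(x) & np.isfinite(y)
            x, y = x[ok], y[ok]
            base = {"roi": roi, "pair": f"{xvar}~{yvar}", "method": method,
                    "n": int(len(x)), "correction": "uncorrected"}
            if len(x) < 3:
                rows.append({**base, "coefficient": np.nan, "p": np.nan,
                             "significant": False, "skipped": True,
                             "reason": "fewer than 3 pairs"})
                continue
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                rows.append({**base, "coefficient": np.nan, "p": np.nan,
                             "significant": False, "skipped": True,
                             "reason": "constant column"})
                continue
            if method == "pearson":
                r, p = stats.pearsonr(x, y)
            else:
                r, p = stats.spearmanr(x, y)
            rows.append({**base, "coefficient": float(r), "p": float(p),
                         "significant": bool(p < alpha), "skipped": False,
                         "reason": ""})
    return pd.DataFrame(rows)
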