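"""Readers, writers and run configuration.

NIfTI is the only image dialect (RAS+ affines); cohorts travel as a
manifest CSV (subject_id, group, scan_path + clinical columns) next to one
NIfTI volume per subject.  All fan-out randomness derives from one global
seed via named child sequences so each stage is reproducible in isolation.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .core import Mask, ScanImage

__all__ = [
    "RunConfig",
    "read_scan",
    "write_scan",
    "read_cohort",
    "write_cohort",
    "stage_seed",
]

VALID_GROUPS = {"control", "patient"}


@dataclass
class RunConfig:
    """All tunable constants of the end-to-end run.

    Defaults are the published analysis constants: 35% intensity mask,
    top-50% variance retention, 1000 bootstrap replicates at a one-sided
    95% percentile interval, alpha 0.005 for clinical correlations and
    0.05 (uncorrected) for the exploratory ROI stage.
    """

    mask_fraction: float = 0.35
    variance_threshold: float = 0.50
    bootstrap_reps: int = 1000
    one_sided_ci: float = 0.95
    alpha_clinical: float = 0.005
    alpha_roi: float = 0.05
    seed: int = 0
    n_controls: int = 16
    n_patients: int = 17
    grid_dims: tuple[int, int, int] = (20, 20, 20)
    effect_size: float = 3.0
    manifest: str | None = None
    out_dir: str = "ssmpca_out"

    def __post_init__(self) -> None:
        for name in ("mask_fraction", "variance_threshold", "one_sided_ci",
                     "alpha_clinical", "alpha_roi"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.bootstrap_reps < 1:
            raise ValueError("bootstrap_reps must be >= 1")
        self.grid_dims = tuple(int(d) for d in self.grid_dims)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["grid_dims"] = list(self.grid_dims)
        return d

    def analysis_dict(self) -> dict:
        """Parameters that determine the results (output location excluded)."""
        d = self.to_dict()
        d.pop("out_dir")
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.analysis_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage child seed (< 2**31) from the global seed."""
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def write_scan(scan: ScanImage, path) -> None:
    nib.save(nib.Nifti1Image(scan.voxels.astype(np.float64), scan.affine), str(path))


def read_scan(path, subject_id: str | None = None) -> ScanImage:
    img = nib.load(str(path))
    return ScanImage(
        subject_id=subject_id or Path(path).stem.replace(".nii", ""),
        voxels=np.asarray(img.dataobj, dtype=float),
        affine=img.affine,
    )


def write_volume(volume: np.ndarray, path, affine=None) -> None:
    """Write a plain 3D array (pattern, mask, stability map) as NIfTI."""
    nib.save(nib.Nifti1Image(np.asarray(volume, dtype=np.float64),
                             np.eye(4) if affine is None else affine), str(path))


def write_cohort(
    scans: list[ScanImage],
    clinical: pd.DataFrame,
    out_dir,
    truth=None,
) -> Path:
    """Write one NIfTI per subject, the clinical CSV and a manifest CSV.

    If a ground truth is given, the pattern volume and the true scores are
    written alongside (``ground_truth_pattern.nii.gz``, ``ground_truth.json``).
    Returns the manifest path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    scan_dir = out_dir / "scans"
    scan_dir.mkdir(exist_ok=True)
    paths = []
    for scan in scans:
        p = scan_dir / f"{scan.subject_id}.nii.gz"
        write_scan(scan, p)
        paths.append(str(p.relative_to(out_dir)))
    manifest = clinical.copy()
    manifest.insert(manifest.columns.get_loc("group") + 1, "scan_path", paths)
    manifest_path = out_dir / "manifest.csv"
    manifest.to_csv(manifest_path, index=False)
    if truth is not None:
        write_volume(truth.pattern, out_dir / "ground_truth_pattern.nii.gz")
        with open(out_dir / "ground_truth.json", "w") as fh:
            json.dump(
                {
                    "true_scores": truth.true_scores.tolist(),
                    "global_offsets": truth.global_offsets.tolist(),
                    "n_support_voxels": int(truth.brain_support.sum()),
                },
                fh,
                indent=2,
            )
    return manifest_path


def read_cohort(manifest_path) -> tuple[list[ScanImage], pd.DataFrame]:
    """Load scans and the clinical table from a manifest CSV.

    The manifest must list subject_id, group and scan_path (relative paths
    are resolved against the manifest's directory).  Scan dimensions are
    validated to be identical; errors name the offending subject.
    """
    manifest_path = Path(manifest_path)
    table = pd.read_csv(manifest_path)
    for col in ("subject_id", "group", "scan_path"):
        if col not in table:
            raise ValueError(f"manifest is missing required column {col!r}")
    bad_groups = set(table["group"]) - VALID_GROUPS
    if bad_groups:
        raise ValueError(f"unknown group label(s): {sorted(bad_groups)}")
    scans = []
    for _, row in table.iterrows():
        p = Path(row["scan_path"])
        if not p.is_absolute():
            p = manifest_path.parent / p
        if not p.exists():
            raise FileNotFoundError(f"subject {row['subject_id']!r}: scan not found at {p}")
        scans.append(read_scan(p, subject_id=str(row["subject_id"])))
    shape = scans[0].shape
    for s in scans:
        if s.shape != shape:
            raise ValueError(
                f"subject {s.subject_id!r}: scan shape {s.shape} differs from {shape}"
            )
    clinical = table.drop(columns=["scan_path"])
    if "label" not in clinical:
        clinical["label"] = (clinical["group"] == "patient").astype(int)
    return scans, clinical
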