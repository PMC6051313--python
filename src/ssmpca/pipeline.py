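"""End-to-end orchestration: derive -> validate -> bootstrap -> clinical -> ROI.

Runs the whole analysis on either a user-supplied cohort (manifest CSV) or
a freshly simulated one, writes every artifact (pattern NIfTI, stable-map
NIfTI, scores CSV, tidy stats CSVs) and a single JSON report stamped with
the config hash.  With a fixed config and seed the report is byte-identical
across runs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bootstrap import bootstrap_patterns, threshold_stable_voxels
from .clinical import compare_groups, correlate_clinical
from .core import build_common_mask, compute_srp, project_score
from .io import RunConfig, stage_seed, write_cohort, write_volume, read_cohort
from .pattern import derive_pattern, zscore_scores
from .roi import roi_correlations, summarize_rois
from .synthetic import CohortParams, make_roi_masks, simulate_clinical, simulate_cohort, simulate_roi_dataset
from .validation import group_ttest, loocv, roc_optimal_cutoff, sens_spec

log = logging.getLogger("ssmpca")

__all__ = ["run_pipeline", "simulate_to_dir"]


def _round_floats(obj, ndigits=10):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def simulate_to_dir(config: RunConfig, out_dir) -> Path:
    """Generate a synthetic cohort per the config and write it to disk."""
    params = CohortParams(
        n_controls=config.n_controls,
        n_patients=config.n_patients,
        grid_dims=config.grid_dims,
        effect_size=config.effect_size,
        seed=stage_seed(config.seed, "cohort"),
    )
    scans, truth, table = simulate_cohort(params)
    clinical = simulate_clinical(
        truth.true_scores, table["label"].to_numpy(), seed=stage_seed(config.seed, "clinical")
    )
    return write_cohort(scans, clinical, out_dir, truth=truth)


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage in order and return the report dict.

    Stages: pattern derivation on the full cohort; LOOCV validation with
    t-test, ROC cutoff and sensitivity/specificity; bootstrap voxel
    stability; clinical group comparisons and z-score correlations
    (patients only); ROI atrophy-metabolism correlations on synthetic ROI
    inputs (skipped when running from a user manifest without grey-matter
    maps).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    fh = logging.FileHandler(out / "run.log")
    log.addHandler(fh)
    cfg_hash = config.config_hash()
    log.info("run config hash %s seed %d", cfg_hash, config.seed)
    report: dict = {"config": config.analysis_dict(), "config_hash": cfg_hash,
                    "package_version": __version__}

    # ---- cohort -----------------------------------------------------------
    if config.manifest:
        scans, clinical = read_cohort(config.manifest)
        truth = None
    else:
        params = CohortParams(
            n_controls=config.n_controls,
            n_patients=config.n_patients,
            grid_dims=config.grid_dims,
            effect_size=config.effect_size,
            seed=stage_seed(config.seed, "cohort"),
        )
        scans, truth, table = simulate_cohort(params)
        clinical = simulate_clinical(
            truth.true_scores, table["label"].to_numpy(),
            seed=stage_seed(config.seed, "clinical"),
        )
    labels = clinical["label"].to_numpy()

    # ---- stage 1: derivation ---------------------------------------------
    try:
        mask = build_common_mask(scans, config.mask_fraction)
        srp = compute_srp(scans, mask, labels)
        model, raw_scores = derive_pattern(srp, config.variance_threshold)
    except Exception as e:
        raise RuntimeError(f"stage 'derive' failed: {e}") from e
    scores = zscore_scores(raw_scores, model.control_ref, srp.subject_ids)
    z = np.array([s.z for s in scores])
    derive_block = {
        "n_subjects": len(scans),
        "n_mask_voxels": mask.n_voxels,
        "selected_components": model.selected_components,
        "logistic_coefficients": model.logistic_coefficients.tolist(),
        "candidate_cumulative_vaf": float(np.sum(model.selection_info["candidate_vaf"])),
        "n_candidates": model.selection_info["n_candidates"],
        "separated": bool(model.selection_info.get("separated", False)),
    }
    if truth is not None:
        tp = truth.pattern[mask.keep]
        derive_block["pattern_truth_correlation"] = float(
            abs(np.corrcoef(model.weights, tp)[0, 1])
        )
    report["derive"] = derive_block
    write_volume(model.weight_volume(), out / "pattern.nii.gz")
    write_volume(mask.keep.astype(float), out / "mask.nii.gz")

    # ---- stage 2: validation ---------------------------------------------
    try:
        cv = loocv(scans, labels, config.mask_fraction, config.variance_threshold)
        t, p = group_ttest(cv.z_scores, labels)
        roc = roc_optimal_cutoff(z, labels)  # cutoff set on derivation scores
        sens, spec = sens_spec(cv.z_scores, labels, roc.optimal_cutoff)
        cv_roc = roc_optimal_cutoff(cv.z_scores, labels)
    except Exception as e:
        raise RuntimeError(f"stage 'validate' failed: {e}") from e
    model.threshold_z = roc.optimal_cutoff
    report["validate"] = {
        "t": t, "p": p,
        "optimal_cutoff_z": roc.optimal_cutoff,
        "derivation_auc": roc.auc,
        "loocv_auc": cv_roc.auc,
        "sensitivity_pct": 100.0 * sens,
        "specificity_pct": 100.0 * spec,
        "n_folds": cv.n_folds,
        "n_fallback_folds": sum(1 for f in cv.fold_info if f["fallback"]),
    }
    scores_df = pd.DataFrame({
        "subject_id": srp.subject_ids,
        "group": np.where(labels == 1, "patient", "control"),
        "raw": raw_scores,
        "z": z,
        "loocv_z": cv.z_scores,
        "config_hash": cfg_hash,
    })
    scores_df.to_csv(out / "scores.csv", index=False)

    # ---- stage 3: bootstrap stability ------------------------------------
    try:
        weights, bmask, _, n_redrawn = bootstrap_patterns(
            scans, labels, n_reps=config.bootstrap_reps,
            seed=stage_seed(config.seed, "bootstrap"),
            mask_fraction=config.mask_fraction,
            variance_threshold=config.variance_threshold,
        )
        boot = threshold_stable_voxels(weights, bmask, config.one_sided_ci, n_redrawn)
    except Exception as e:
        raise RuntimeError(f"stage 'bootstrap' failed: {e}") from e
    report["bootstrap"] = {
        "n_reps": boot.n_reps,
        "n_redrawn": boot.n_redrawn,
        **boot.counts(),
        "n_mask_voxels": bmask.n_voxels,
    }
    write_volume(boot.stable_volume(), out / "stable_pattern.nii.gz")

    # ---- stage 4: clinical statistics ------------------------------------
    try:
        groups_df = compare_groups(clinical)
        pat = labels == 1
        corr_df = correlate_clinical(
            cv.z_scores[pat], clinical.loc[pat].reset_index(drop=True),
            alpha=config.alpha_clinical,
        )
    except Exception as e:
        raise RuntimeError(f"stage 'clinical' failed: {e}") from e
    groups_df.to_csv(out / "group_comparisons.csv", index=False)
    corr_df.to_csv(out / "clinical_correlations.csv", index=False)
    sig = corr_df[corr_df["significant"] == True]  # noqa: E712
    report["clinical"] = {
        "alpha": config.alpha_clinical,
        "n_variables": int(len(corr_df)),
        "significant_variables": sig["variable"].tolist(),
        "sara_spearman_rho": _lookup(corr_df, "sara_total"),
    }

    # ---- stage 5: ROI correlations ---------------------------------------
    if truth is not None:
        try:
            fdg, gm, rois, roi_clin, _ = simulate_roi_dataset(
                n_subjects=config.n_patients,
                grid_dims=config.grid_dims,
                seed=stage_seed(config.seed, "roi"),
            )
            summary = summarize_rois(fdg, gm, rois)
            roi_df = roi_correlations(summary, roi_clin, alpha=config.alpha_roi)
        except Exception as e:
            raise RuntimeError(f"stage 'roi' failed: {e}") from e
        roi_df.to_csv(out / "roi_correlations.csv", index=False)
        gm_fdg = roi_df[(roi_df["pair"] == "gm_volume~uptake") & ~roi_df["skipped"]]
        report["roi"] = {
            "alpha": config.alpha_roi,
            "n_rois": int(summary["roi"].nunique()),
            "flagged_gm_fdg_rois": gm_fdg.loc[gm_fdg["significant"], "roi"].tolist(),
        }
    else:
        report["roi"] = {"skipped": "no grey-matter maps available for this cohort"}

    report = _round_floats(report)
    with open(out / "report.json", "w") as fh2:
        json.dump(report, fh2, indent=2, sort_keys=True)
    log.removeHandler(fh)
    fh.close()
    return report


def _lookup(corr_df: pd.DataFrame, variable: str):
    row = corr_df[corr_df["variable"] == variable]
    return float(row["coefficient"].iloc[0]) if len(row) else None
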