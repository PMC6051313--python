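"""Minimal figure export: ROC curve and orthogonal slices of a voxel map."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

__all__ = ["plot_roc", "save_orthoslices"]


def plot_roc(roc, path) -> None:
    """One-panel ROC curve with the Youden-optimal cutoff marked."""
    order = np.argsort(1 - roc.specificity)
    fpr = (1 - roc.specificity)[order]
    tpr = roc.sensitivity[order]
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(fpr, tpr, drawstyle="steps-post", color="C0")
    ax.plot([0, 1], [0, 1], ls="--", color="grey", lw=0.8)
    i = int(np.argmin(np.abs(roc.thresholds - roc.optimal_cutoff)))
    ax.plot(1 - roc.specificity[i], roc.sensitivity[i], "o", color="C3",
            label=f"cutoff z = {roc.optimal_cutoff:.2f}")
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.set_title(f"AUC = {roc.auc:.3f}")
    ax.legend(loc="lower right", frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def save_orthoslices(volume: np.ndarray, path, title: str = "") -> None:
    """Mid-volume axial/coronal/sagittal slices with a symmetric color scale."""
    vmax = np.abs(volume).max() or 1.0
    fig, axes = plt.subplots(1, 3, figsize=(9, 3))
    mids = [d // 2 for d in volume.shape]
    slices = [volume[mids[0], :, :], volume[:, mids[1], :], volume[:, :, mids[2]]]
    for ax, sl, name in zip(axes, slices, ("sagittal", "coronal", "axial")):
        im = ax.imshow(sl.T, origin="lower", cmap="RdBu_r", vmin=-vmax, vmax=vmax)
        ax.set_title(name, fontsize=9)
        ax.axis("off")
    fig.colorbar(im, ax=axes, shrink=0.8)
    if title:
        fig.suptitle(title)
    fig.savefig(path, dpi=150)
    plt.close(fig)
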