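"""Static figure outputs: SMART plots, dendrogram, ROC."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from scipy.cluster import hierarchy

from smartscan.clustering import ClusterResult
from smartscan.nullsim import ProbabilityMap
from smartscan.scan import DensityMap, ScanResult
from smartscan.validation import ValidationResult


def smart_model_plot(scan: ScanResult, path: str | Path) -> None:
    """Model positions: yellow squares significant, black dots not."""
    fig, ax = plt.subplots(figsize=(6, 5))
    pos = np.array([s.position for s in scan.subsets])
    sig = np.array([s.significant for s in scan.subsets])
    if (~sig).any():
        ax.plot(pos[~sig, 0], pos[~sig, 1], "k.", ms=4, label="non-significant")
    if sig.any():
        ax.plot(pos[sig, 0], pos[sig, 1], "s", color="gold", mec="black",
                ms=6, label="significant (CV-ANOVA p < 0.05)")
    ax.set_xlabel("time to diagnosis (years)")
    ax.set_ylabel("time between repeated samples (years)")
    ax.invert_xaxis()
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def _raster_extent(dmap) -> tuple[float, float, float, float]:
    dt = dmap.ttd_centers[1] - dmap.ttd_centers[0] if len(dmap.ttd_centers) > 1 else 0.25
    db = dmap.tbs_centers[1] - dmap.tbs_centers[0] if len(dmap.tbs_centers) > 1 else 0.25
    return (
        dmap.ttd_centers[0] - dt / 2, dmap.ttd_centers[-1] + dt / 2,
        dmap.tbs_centers[0] - db / 2, dmap.tbs_centers[-1] + db / 2,
    )


def observation_plot(
    dmap: DensityMap, coords: np.ndarray | None, path: str | Path, signed: bool = False
) -> None:
    """Density of overlaid significant-subset ellipses, plus observations."""
    fig, ax = plt.subplots(figsize=(6, 5))
    cmap, vmin = ("RdBu_r", -np.abs(dmap.counts).max() or 1) if signed else ("Blues", 0)
    im = ax.imshow(dmap.counts, origin="lower", aspect="auto", cmap=cmap,
                   vmin=vmin, extent=_raster_extent(dmap))
    if coords is not None:
        ax.plot(coords[:, 0], coords[:, 1], "k.", ms=5)
    fig.colorbar(im, ax=ax, label="overlaid significant subsets")
    ax.set_xlabel("time to diagnosis (years)")
    ax.set_ylabel("time between repeated samples (years)")
    ax.invert_xaxis()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def probability_plot(pmap: ProbabilityMap, path: str | Path) -> None:
    """Color-banded false-positive probability map."""
    bounds = [0.0, 0.001, 0.01, 0.05, 0.10, 0.20, 1.0]
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.contourf(pmap.ttd_centers, pmap.tbs_centers, pmap.p_hat,
                     levels=bounds, cmap="viridis_r")
    fig.colorbar(im, ax=ax, label="null probability")
    ax.set_xlabel("time to diagnosis (years)")
    ax.set_ylabel("time between repeated samples (years)")
    ax.invert_xaxis()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def dendrogram_plot(result: ClusterResult, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(8, 4))
    if result.linkage is not None:
        hierarchy.dendrogram(result.linkage, ax=ax, no_labels=True,
                             color_threshold=result.cut_height)
        if np.isfinite(result.cut_height):
            ax.axhline(result.cut_height, color="red", ls="--", lw=1,
                       label="simulated 95% limit")
            ax.legend(fontsize=8)
    ax.set_ylabel("1 - cosine similarity")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def roc_plot(result: ValidationResult, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot(result.fpr, result.tpr, "-", lw=2,
            label=f"AUC = {result.auc:.2f} (p = {result.p_rank:.3g})")
    ax.plot([0, 1], [0, 1], "k--", lw=1)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
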