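"""Minimal figure helpers (PNG output, Agg backend)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .qcstats import PurityReport, SaturationCurve

__all__ = [
    "plot_purity_histogram",
    "plot_barcode_rank",
    "plot_saturation",
    "plot_phase_heatmap",
    "plot_embedding",
]


def plot_purity_histogram(report: PurityReport, path: str) -> None:
    fig, ax = plt.subplots(figsize=(5, 3.5))
    centers = 0.5 * (report.bin_edges[:-1] + report.bin_edges[1:])
    ax.bar(centers, report.bin_counts, width=np.diff(report.bin_edges), color="steelblue")
    ax.set_xlabel("fraction of molecules aligned to human")
    ax.set_ylabel("barcodes")
    ax.set_title(
        f"median purity {report.median_purity:.3f}, "
        f"multiplets {100 * report.multiplet_fraction:.2f}%"
    )
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_barcode_rank(ranks: pd.DataFrame, path: str, knee_rank: int | None = None) -> None:
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.loglog(ranks["rank"], ranks["molecules"], drawstyle="steps-post")
    if knee_rank:
        ax.axvline(knee_rank, color="crimson", ls="--", lw=1)
    ax.set_xlabel("barcode rank")
    ax.set_ylabel("molecules")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_saturation(curve: SaturationCurve, path: str) -> None:
    fig, axes = plt.subplots(1, 2, figsize=(8, 3.5))
    t = curve.table
    axes[0].plot(t["reads"], t["molecules"], marker="o")
    axes[0].set_xlabel("reads sampled")
    axes[0].set_ylabel("molecules detected")
    axes[1].plot(t["reads"], t["genes"], marker="o", color="darkorange")
    axes[1].set_xlabel("reads sampled")
    axes[1].set_ylabel("genes detected")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_phase_heatmap(score_df: pd.DataFrame, assignments: pd.DataFrame, path: str) -> None:
    """Cells (ordered by pattern and within-class key) x phases heatmap."""
    ordered = score_df.loc[assignments.index]
    fig, ax = plt.subplots(figsize=(4, 6))
    im = ax.imshow(ordered.to_numpy(), aspect="auto", cmap="RdBu_r", vmin=-3, vmax=3)
    ax.set_xticks(range(len(ordered.columns)), ordered.columns, rotation=45)
    ax.set_ylabel("cells (cycle-ordered)")
    fig.colorbar(im, ax=ax, label="phase score (z)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_embedding(cells: pd.DataFrame, path: str, color: pd.Series | None = None) -> None:
    fig, ax = plt.subplots(figsize=(4.5, 4))
    if color is None:
        c = cells["cluster"]
        sc = ax.scatter(cells["x"], cells["y"], c=c, s=8, cmap="tab10")
    else:
        sc = ax.scatter(cells["x"], cells["y"], c=color, s=8, cmap="viridis")
        fig.colorbar(sc, ax=ax)
    ax.set_xlabel("t-SNE 1")
    ax.set_ylabel("t-SNE 2")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
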