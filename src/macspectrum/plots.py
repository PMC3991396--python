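"""Static matplotlib renderings of pipeline artifacts (side effects only).

Plots are never inputs to any computation; every quantitative result is
written as plain text elsewhere.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def plot_spectrum(vectors, path) -> None:
    """3-D arrows from the baseline origin to each condition-cluster centroid."""
    fig = plt.figure(figsize=(6, 6))
    ax = fig.add_subplot(projection="3d")
    for v in vectors:
        if v.is_baseline:
            ax.scatter([0], [0], [0], color="black", s=40, label="baseline")
            continue
        ax.quiver(0, 0, 0, *v.vector, arrow_length_ratio=0.1)
        ax.text(*v.vector, f"c{v.cluster_id}", fontsize=8)
    ax.set_xlabel("x")
    ax.set_ylabel("y")
    ax.set_zlabel("z")
    ax.set_title("Activation spectrum (cluster mean vectors)")
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_ccm(ccm, path) -> None:
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(ccm.z_matrix.to_numpy(), cmap="RdBu_r", vmin=-ccm.z_clip, vmax=ccm.z_clip)
    ax.set_xticks(range(len(ccm.conditions)), ccm.conditions, rotation=90, fontsize=7)
    ax.set_yticks(range(len(ccm.conditions)), ccm.conditions, fontsize=7)
    fig.colorbar(im, ax=ax, label="standardized r")
    ax.set_title("Condition correlation matrix")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_module_trait_heatmap(r: pd.DataFrame, path) -> None:
    fig, ax = plt.subplots(figsize=(max(4, 0.5 * r.shape[1]), max(3, 0.35 * r.shape[0])))
    im = ax.imshow(r.to_numpy(), cmap="RdBu_r", vmin=-1, vmax=1, aspect="auto")
    ax.set_xticks(range(r.shape[1]), r.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(r.shape[0]), [f"M{m}" for m in r.index], fontsize=7)
    fig.colorbar(im, ax=ax, label="eigengene-trait r")
    ax.set_title("Module eigengene vs condition")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_volcano(results: pd.DataFrame, path, nes_min: float = 1.0, p_max: float = 0.05) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    p = np.maximum(results["p"].to_numpy(dtype=float), 1e-6)
    nes = results["nes"].to_numpy(dtype=float)
    up = (nes > nes_min) & (p < p_max)
    dn = (nes < -nes_min) & (p < p_max)
    ax.scatter(nes[~(up | dn)], -np.log10(p[~(up | dn)]), c="grey", s=18)
    ax.scatter(nes[up], -np.log10(p[up]), c="red", s=24, label="enriched")
    ax.scatter(nes[dn], -np.log10(p[dn]), c="blue", s=24, label="depleted")
    ax.axvline(nes_min, ls="--", lw=0.8, c="k")
    ax.axvline(-nes_min, ls="--", lw=0.8, c="k")
    ax.axhline(-np.log10(p_max), ls="--", lw=0.8, c="k")
    ax.set_xlabel("NES")
    ax.set_ylabel("-log10 p")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_som_portraits(som, path) -> None:
    """One grid heatmap per condition: each unit colored by its codebook value."""
    n_feat = len(som.feature_names)
    ncol = min(4, n_feat)
    nrow = int(np.ceil(n_feat / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(2.2 * ncol, 2.0 * nrow), squeeze=False)
    books = som.codebooks.reshape(som.grid_w, som.grid_h, n_feat)
    vmax = np.abs(som.codebooks).max() or 1.0
    for i, name in enumerate(som.feature_names):
        ax = axes[i // ncol][i % ncol]
        ax.imshow(books[:, :, i].T, cmap="RdBu_r", vmin=-vmax, vmax=vmax, origin="lower")
        ax.set_title(name, fontsize=7)
        ax.set_xticks([])
        ax.set_yticks([])
    for j in range(n_feat, nrow * ncol):
        axes[j // ncol][j % ncol].axis("off")
    fig.suptitle("SOM portraits (unit codebooks per condition)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
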