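"""Self-organizing maps over gene expression portraits and exclusive-marker
calling.

Genes are z-scored (shape, not level, drives the map), embedded on a
rectangular SOM grid trained in batch mode with a linearly shrinking Gaussian
neighborhood, and the unit codebooks are hierarchically meta-clustered. A
separate margin criterion calls genes selectively elevated in exactly one
stimulation condition — the single-stimulus markers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .containers import ExpressionMatrix


@dataclass
class SOMMap:
    grid_w: int
    grid_h: int
    codebooks: np.ndarray  # (grid_w * grid_h, n_features)
    bmu_of: pd.Series  # gene -> unit index (row-major grid order)
    feature_names: list[str]
    unit_clusters: np.ndarray | None = None  # unit -> meta-cluster label

    @property
    def n_units(self) -> int:
        return self.grid_w * self.grid_h

    def unit_coords(self) -> np.ndarray:
        xs, ys = np.meshgrid(np.arange(self.grid_w), np.arange(self.grid_h), indexing="ij")
        return np.column_stack([xs.ravel(), ys.ravel()]).astype(float)


def standardize_genes(profiles: pd.DataFrame) -> pd.DataFrame:
    """z-score each gene's profile; constant genes map to all-zero rows."""
    arr = profiles.to_numpy(dtype=float)
    mu = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, keepdims=True)
    sd = np.where(sd == 0, 1.0, sd)
    return pd.DataFrame((arr - mu) / sd, index=profiles.index, columns=profiles.columns)


def _pca_init(data: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Deterministic codebook initialization from the first two PCs.

    The grid is stretched along PC1/PC2 to cover ±2 sd of the projected data.
    """
    centered = data - data.mean(axis=0)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    n = max(1, data.shape[0] - 1)
    comps = vt[:2]
    sds = s[:2] / np.sqrt(n)
    # enforce a sign convention so initialization is orientation-stable
    for i in range(comps.shape[0]):
        j = np.argmax(np.abs(comps[i]))
        if comps[i, j] < 0:
            comps[i] = -comps[i]
    spans = []
    for axis in range(2):
        c = coords[:, axis]
        rng_ = c.max() - c.min()
        u = (c - c.min()) / rng_ * 2 - 1 if rng_ > 0 else np.zeros_like(c)
        spans.append(u)
    book = data.mean(axis=0)[None, :] + np.zeros((coords.shape[0], data.shape[1]))
    for axis in range(min(2, comps.shape[0])):
        book = book + np.outer(spans[axis] * 2.0 * sds[axis], comps[axis])
    return book


def som_fit(
    condition_profiles: pd.DataFrame,
    grid_w: int = 10,
    grid_h: int = 10,
    epochs: int = 50,
    seed: int = 0,
    standardize: bool = True,
) -> SOMMap:
    """Train a batch SOM on genes x conditions profiles.

    Gaussian neighborhood radius shrinks linearly from ``max(w, h)/2`` to 0.5
    over the epochs; codebooks start from a PCA plane so the fit is
    deterministic (``seed`` is accepted for interface symmetry but the batch
    algorithm consumes no randomness). Each gene is assigned the Euclidean
    best-matching unit.
    """
    if grid_w * grid_h < 2:
        raise ValueError("SOM grid must have >= 2 units")
    if epochs < 1:
        raise ValueError("epochs must be >= 1")
    profiles = standardize_genes(condition_profiles) if standardize else condition_profiles
    data = profiles.to_numpy(dtype=float)
    n_units = grid_w * grid_h
    if n_units > data.shape[0]:
        warnings.warn(f"more SOM units ({n_units}) than genes ({data.shape[0]}); proceeding")
    coords = np.meshgrid(np.arange(grid_w), np.arange(grid_h), indexing="ij")
    coords = np.column_stack([c.ravel() for c in coords]).astype(float)
    book = _pca_init(data, coords)

    grid_d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
    sigma0, sigma1 = max(grid_w, grid_h) / 2.0, 0.5
    for epoch in range(epochs):
        frac = epoch / max(1, epochs - 1)
        sigma = sigma0 + (sigma1 - sigma0) * frac
        d2 = ((data[:, None, :] - book[None, :, :]) ** 2).sum(-1)
        bmu = d2.argmin(axis=1)
        h = np.exp(-grid_d2[:, bmu] / (2 * sigma**2))  # units x genes
        weights = h.sum(axis=1, keepdims=True)
        weights = np.where(weights == 0, 1.0, weights)
        book = (h @ data) / weights
    # final fine-tuning step in the sigma -> 0 limit: each occupied unit
    # becomes the centroid of its assigned genes (the k-means step)
    d2 = ((data[:, None, :] - book[None, :, :]) ** 2).sum(-1)
    bmu = d2.argmin(axis=1)
    for unit in range(n_units):
        sel = bmu == unit
        if sel.any():
            book[unit] = data[sel].mean(axis=0)
    d2 = ((data[:, None, :] - book[None, :, :]) ** 2).sum(-1)
    bmu = pd.Series(d2.argmin(axis=1), index=profiles.index, name="bmu")
    return SOMMap(grid_w, grid_h, book, bmu, list(condition_profiles.columns))


def quantization_error(som: SOMMap, condition_profiles: pd.DataFrame, standardize: bool = True) -> float:
    profiles = standardize_genes(condition_profiles) if standardize else condition_profiles
    data = profiles.to_numpy(dtype=float)
    d = np.linalg.norm(data - som.codebooks[som.bmu_of.to_numpy()], axis=1)
    return float(d.mean())


def som_metaclusters(som: SOMMap, k: int, linkage_method: str = "average") -> SOMMap:
    """Average-linkage hierarchical clustering of the unit codebooks, cut at k."""
    if k > som.n_units:
        raise ValueError(f"k={k} exceeds number of units ({som.n_units})")
    d = np.linalg.norm(som.codebooks[:, None, :] - som.codebooks[None, :, :], axis=-1)
    link = hierarchy.linkage(squareform(d, checks=False), method=linkage_method)
    labels = hierarchy.fcluster(link, t=k, criterion="maxclust") - 1
    return SOMMap(som.grid_w, som.grid_h, som.codebooks, som.bmu_of, som.feature_names, labels)


def exclusive_markers(
    matrix: ExpressionMatrix,
    condition: str,
    margin_min: float = 1.0,
) -> pd.DataFrame:
    """Genes selectively elevated in one stimulation condition.

    A gene qualifies when its mean in the target condition exceeds the
    maximum mean over every other condition by at least ``margin_min`` log2
    units; qualifying genes are ranked by descending margin. A gene elevated
    comparably in two conditions fails the margin in both and appears in
    neither table.
    """
    if condition not in matrix.conditions:
        raise ValueError(f"unknown condition {condition!r}")
    if len(matrix.conditions) < 2:
        raise ValueError("need >= 2 conditions")
    means = matrix.condition_means()
    target = means[condition]
    others = means.drop(columns=[condition])
    margin = target - others.max(axis=1)
    table = pd.DataFrame(
        {
            "condition": condition,
            "mean_target": target,
            "max_other": others.max(axis=1),
            "margin": margin,
        }
    )
    table = table[table["margin"] >= margin_min].sort_values(
        ["margin", "mean_target"], ascending=[False, False], kind="stable"
    )
    table["rank"] = np.arange(1, len(table) + 1)
    return table
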