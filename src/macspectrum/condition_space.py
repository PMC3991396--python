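"""Condition correlation matrix (CCM) and the 3-D activation-spectrum model.

Conditions are summarized by their mean profile over the most variable genes;
the pairwise Pearson matrix is hierarchically clustered (average linkage on
1 - r) into k activation clusters. Each cluster's samples are then averaged
in the 3-D coregulation layout and expressed as a displacement vector from
the baseline-sample centroid — the baseline is the origin of the spectrum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .containers import ExpressionMatrix, SpectrumVector, baseline_condition
from .preprocess import top_variable_genes


@dataclass
class CCM:
    """Condition x condition Pearson matrix with its clustering."""

    conditions: list[str]
    r_matrix: pd.DataFrame
    z_matrix: pd.DataFrame  # standardized display values (affine, clipped)
    linkage: np.ndarray
    cluster_of: dict[str, int]
    z_clip: float


def condition_ccm(
    matrix: ExpressionMatrix,
    top_n: int = 1000,
    k: int = 10,
    linkage_method: str = "average",
    z_clip: float = 2.78,
) -> CCM:
    """Correlation-coefficient matrix over per-condition mean profiles.

    Profiles use the ``top_n`` most variable genes; hierarchical clustering of
    1 - r with the given linkage is cut to ``k`` clusters. The display matrix
    z-scores the off-diagonal r values and clips at ``±z_clip`` (display only,
    never used in computation). Cluster ids are relabelled so that equal
    partitions get equal ids regardless of condition order (smallest condition
    index first).
    """
    conditions = matrix.conditions
    if k > len(conditions):
        raise ValueError(f"k={k} exceeds number of conditions ({len(conditions)})")
    singletons = [c for c in conditions if len(matrix.samples_of(c)) < 2]
    if singletons:
        warnings.warn(f"condition(s) with a single sample: {singletons}")
    top = top_variable_genes(matrix, min(top_n, matrix.n_genes))
    profiles = matrix.subset_genes(top).condition_means()  # genes x conditions
    r = np.corrcoef(profiles.to_numpy(), rowvar=False)
    r_frame = pd.DataFrame(r, index=conditions, columns=conditions)

    off = r[~np.eye(len(conditions), dtype=bool)]
    mu, sd = off.mean(), off.std()
    z = (r - mu) / (sd if sd > 0 else 1.0)
    z_frame = pd.DataFrame(np.clip(z, -z_clip, z_clip), index=conditions, columns=conditions)

    dist = np.clip(1.0 - r, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    link = hierarchy.linkage(squareform(dist, checks=False), method=linkage_method)
    raw = hierarchy.fcluster(link, t=k, criterion="maxclust")
    relabel: dict[int, int] = {}
    cluster_of = {}
    for c, lab in zip(conditions, raw):
        if lab not in relabel:
            relabel[lab] = len(relabel)
        cluster_of[c] = relabel[lab]
    return CCM(conditions, r_frame, z_frame, link, cluster_of, z_clip)


def spectrum_vectors(
    layout: dict[str, np.ndarray],
    design: pd.DataFrame,
    ccm: CCM,
) -> list[SpectrumVector]:
    """Mean 3-D displacement of each CCM cluster from the baseline centroid.

    Samples inherit the cluster of their condition; a cluster's vector is the
    mean of its member coordinates minus the mean of the baseline-condition
    sample coordinates. The baseline cluster maps to (0,0,0) only when the
    baseline condition is the sole member of its cluster; either way the
    origin is the baseline centroid.
    """
    base = baseline_condition(design)
    base_cluster = ccm.cluster_of[base]
    coords = {s: np.asarray(p, dtype=float) for s, p in layout.items()}
    missing = [s for s in design.index if s not in coords]
    if missing:
        raise ValueError(f"sample(s) without layout coordinates: {missing[:10]}")
    base_samples = list(design.index[design["condition"] == base])
    origin = np.mean([coords[s] for s in base_samples], axis=0)

    vectors = []
    for cluster_id in sorted(set(ccm.cluster_of.values())):
        members = [
            s
            for s in design.index
            if ccm.cluster_of[str(design.loc[s, "condition"])] == cluster_id
        ]
        if not members:
            raise ValueError(f"CCM cluster {cluster_id} has no laid-out samples")
        centroid = np.mean([coords[s] for s in members], axis=0)
        vectors.append(
            SpectrumVector(
                cluster_id=cluster_id,
                members=members,
                vector=centroid - origin,
                is_baseline=cluster_id == base_cluster,
            )
        )
    return vectors


def spectrum_angles(vectors: list[SpectrumVector], zero_tol: float = 1e-12) -> pd.DataFrame:
    """Pairwise angles (degrees) between non-zero spectrum vectors.

    Zero-magnitude vectors (the baseline) are excluded; with fewer than two
    non-zero vectors there is no angle to report and an error is raised.
    """
    nonzero = [v for v in vectors if v.magnitude > zero_tol]
    if len(nonzero) < 2:
        raise ValueError("need >= 2 non-zero vectors to compute angles")
    rows = []
    for i, a in enumerate(nonzero):
        for b in nonzero[i + 1 :]:
            cosang = float(np.clip(np.dot(a.direction, b.direction), -1.0, 1.0))
            rows.append(
                {
                    "cluster_a": a.cluster_id,
                    "cluster_b": b.cluster_id,
                    "angle_deg": float(np.degrees(np.arccos(cosang))),
                }
            )
    return pd.DataFrame(rows)
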