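"""Weighted gene coexpression module detection and module-trait correlation.

The classic soft-thresholding workflow: raise |Pearson r| to a power chosen
for approximate scale-free topology, smooth the adjacency into the
topological overlap measure (TOM), cluster 1 - TOM with average linkage,
cut the tree statically, assign undersized branches to the unassigned pool
(module 0), and merge modules whose eigengenes are nearly collinear. The
module eigengene — first principal component of the gene-standardized
submatrix — summarizes each module per sample and is correlated against
one-hot condition indicators to map modules to the stimuli that drive them.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix, GeneModule


def adjacency_matrix(matrix: ExpressionMatrix, power: float = 6.0) -> pd.DataFrame:
    """Unsigned weighted adjacency |r|^power with zero diagonal."""
    arr = matrix.values.to_numpy(dtype=float)
    sd = arr.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(arr)
    r = np.where(np.isfinite(r), r, 0.0)  # constant genes: no coexpression
    a = np.abs(r) ** power
    np.fill_diagonal(a, 0.0)
    if (sd == 0).any():
        a[sd == 0, :] = 0.0
        a[:, sd == 0] = 0.0
    return pd.DataFrame(a, index=matrix.values.index, columns=matrix.values.index)


def scale_free_fit(adjacency: pd.DataFrame, n_bins: int = 10) -> float:
    """Signed R^2 of the log-log degree-distribution fit (WGCNA's criterion).

    Connectivity k is binned; log10(mean frequency) is regressed on
    log10(mean k). The R^2 is signed by the slope: scale-free topology
    requires a *decreasing* frequency in k, so positive fit means slope < 0.
    """
    k = adjacency.to_numpy().sum(axis=1)
    k = k[k > 0]
    if k.size < 2:
        return 0.0
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    which = np.digitize(k, edges[1:-1])
    xs, ys = [], []
    for b in range(n_bins):
        sel = which == b
        if sel.sum() == 0:
            continue
        xs.append(k[sel].mean())
        ys.append(sel.mean())
    xs, ys = np.log10(np.asarray(xs)), np.log10(np.asarray(ys))
    if len(xs) < 3 or np.allclose(xs, xs[0]):
        return 0.0
    slope, _, r_value, _, _ = stats.linregress(xs, ys)
    return float(-np.sign(slope) * r_value**2)


def pick_soft_threshold(
    matrix: ExpressionMatrix,
    powers: list[float] = (1, 2, 3, 4, 5, 6, 7, 8, 10, 12, 14, 16, 18, 20),
    target_r2: float = 0.8,
    min_mean_k: float = 1.0,
) -> tuple[float, pd.DataFrame]:
    """Smallest power whose scale-free fit reaches ``target_r2``.

    When no candidate reaches the target (planted-block covariances, for
    instance, are not scale-free at any power) the fallback takes the best
    fit among powers that keep mean connectivity >= ``min_mean_k`` — raising
    the power indefinitely always "improves" the log-log fit by emptying the
    network, which is not a usable adjacency. Returns the chosen power and
    the per-power diagnostics (fit, mean connectivity).
    """
    if len(powers) == 0:
        raise ValueError("powers must be non-empty")
    if matrix.n_genes < 10:
        raise ValueError("scale-free fit is meaningless below 10 genes")
    rows = []
    for p in powers:
        a = adjacency_matrix(matrix, power=p)
        rows.append({"power": p, "fit_r2": scale_free_fit(a), "mean_k": float(a.to_numpy().sum(axis=1).mean())})
    diag = pd.DataFrame(rows)
    ok = diag[diag["fit_r2"] >= target_r2]
    if len(ok):
        chosen = float(ok.iloc[0]["power"])
    else:
        usable = diag[diag["mean_k"] >= min_mean_k]
        if not len(usable):
            usable = diag.iloc[[0]]
        chosen = float(usable.loc[usable["fit_r2"].idxmax(), "power"])
        warnings.warn(f"no power reached scale-free fit {target_r2}; using best usable fit (power={chosen})")
    return chosen, diag


def topological_overlap(adjacency: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij).

    Requires a symmetric adjacency with entries in [0, 1] and a zero
    diagonal; the result is symmetric with unit diagonal and entries in
    [0, 1].
    """
    frame = isinstance(adjacency, pd.DataFrame)
    a = adjacency.to_numpy(dtype=float) if frame else np.asarray(adjacency, dtype=float)
    if a.shape[0] != a.shape[1] or not np.allclose(a, a.T):
        raise ValueError("adjacency must be square and symmetric")
    if np.diag(a).any():
        raise ValueError("adjacency diagonal must be zero")
    if a.min() < 0 or a.max() > 1:
        raise ValueError("adjacency entries must lie in [0, 1]")
    k = a.sum(axis=1)
    shared = a @ a
    num = shared + a
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = num / denom
    np.fill_diagonal(tom, 1.0)
    if frame:
        return pd.DataFrame(tom, index=adjacency.index, columns=adjacency.columns)
    return tom


def module_eigengene(matrix: ExpressionMatrix, genes: list[str]) -> tuple[pd.Series, float]:
    """First principal component of the gene-standardized module submatrix.

    Returns the per-sample eigengene (unit norm) and the fraction of variance
    it explains. The sign is chosen so the eigengene correlates positively
    with the module's mean standardized profile; if that correlation is
    numerically zero (perfectly antagonistic halves) the tie is broken by
    aligning with the first gene's profile.
    """
    if len(genes) < 2:
        raise ValueError("module must contain >= 2 genes")
    sub = matrix.values.loc[list(genes)].to_numpy(dtype=float)
    mu = sub.mean(axis=1, keepdims=True)
    sd = sub.std(axis=1, keepdims=True)
    if (sd == 0).all():
        raise ValueError("module submatrix has rank 0 (all genes constant)")
    sd = np.where(sd == 0, 1.0, sd)
    z = (sub - mu) / sd
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    if not s.size or s[0] == 0:
        raise ValueError("module submatrix has rank 0")
    eig = vt[0]
    var_explained = float(s[0] ** 2 / (s**2).sum())
    mean_profile = z.mean(axis=0)
    align = float(np.dot(eig, mean_profile))
    if abs(align) < 1e-10:
        align = float(np.dot(eig, z[0]))
    if align < 0:
        eig = -eig
    return pd.Series(eig, index=matrix.samples, name="eigengene"), var_explained


def _build_module(matrix: ExpressionMatrix, module_id: int, genes: list[str]) -> GeneModule:
    eig, ve = module_eigengene(matrix, genes)
    sub = matrix.values.loc[genes].to_numpy(dtype=float)
    sd = sub.std(axis=1)
    kme = np.zeros(len(genes))
    e = eig.to_numpy()
    ok = sd > 0
    if e.std() > 0 and ok.any():
        zs = (sub[ok] - sub[ok].mean(axis=1, keepdims=True)) / sub[ok].std(axis=1, keepdims=True)
        ez = (e - e.mean()) / e.std()
        kme[ok] = (zs * ez[None, :]).mean(axis=1)
    return GeneModule(module_id, list(genes), eig, ve, pd.Series(kme, index=genes, name="kME"))


def detect_modules(
    matrix: ExpressionMatrix,
    tom: pd.DataFrame,
    min_size: int = 30,
    cut_height: float = 0.95,
    merge_r: float = 0.8,
) -> list[GeneModule]:
    """Static-cut module detection on 1 - TOM with eigengene merging.

    Average-linkage hierarchical clustering of the TOM dissimilarity, a
    static cut at ``cut_height``, branches smaller than ``min_size`` dropped
    to the unassigned pool (module 0, by convention "grey", not returned),
    then iterative merging of module pairs whose eigengenes correlate above
    ``merge_r`` until no pair qualifies. Module ids are 1..M by decreasing
    size.
    """
    if min_size < 3:
        raise ValueError("min_size must be >= 3")
    genes = list(tom.index)
    d = 1.0 - tom.to_numpy(dtype=float)
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, None)
    link = hierarchy.linkage(squareform(d, checks=False), method="average")
    labels = hierarchy.fcluster(link, t=cut_height, criterion="distance")
    groups: dict[int, list[str]] = {}
    for g, lab in zip(genes, labels):
        groups.setdefault(int(lab), []).append(g)
    members = [gl for gl in groups.values() if len(gl) >= min_size]
    if not members:
        warnings.warn("no branch reached min_size; all genes unassigned")
        return []

    # iterative eigengene merging until fixpoint
    while True:
        eigs = [module_eigengene(matrix, gl)[0].to_numpy() for gl in members]
        merged = False
        best = (None, merge_r)
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                r = float(np.corrcoef(eigs[i], eigs[j])[0, 1])
                if r > best[1]:
                    best = ((i, j), r)
        if best[0] is not None:
            i, j = best[0]
            members[i] = members[i] + members[j]
            del members[j]
            merged = True
        if not merged:
            break

    members.sort(key=lambda gl: (-len(gl), gl[0]))
    return [_build_module(matrix, mid + 1, gl) for mid, gl in enumerate(members)]


def module_assignments(modules: list[GeneModule], genes: list[str]) -> pd.Series:
    """Gene -> module id (0 for unassigned), aligned to ``genes``."""
    label = {g: m.module_id for m in modules for g in m.genes}
    return pd.Series([label.get(g, 0) for g in genes], index=genes, name="module")


def module_trait_correlation(
    modules: list[GeneModule],
    design: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pearson r of each module eigengene against one-hot condition traits.

    Returns (r, p, q) frames of shape modules x conditions; p is the
    two-sided Student-t p-value of each correlation and q is BH across the
    full grid. Constant eigengenes yield r = 0, p = 1.
    """
    if not modules:
        raise ValueError("no modules to correlate")
    conditions = list(dict.fromkeys(design["condition"].astype(str)))
    if len(conditions) < 2:
        raise ValueError("need >= 2 conditions")
    singles = [c for c in conditions if (design["condition"] == c).sum() < 2]
    if singles:
        warnings.warn(f"single-sample condition(s): {singles}")
    n = len(design)
    rows_r, rows_p = [], []
    for mod in modules:
        e = mod.eigengene.loc[design.index].to_numpy()
        r_row, p_row = [], []
        for c in conditions:
            ind = (design["condition"] == c).to_numpy(dtype=float)
            if e.std() == 0 or ind.std() == 0:
                r_row.append(0.0)
                p_row.append(1.0)
                continue
            r = float(np.corrcoef(e, ind)[0, 1])
            r = float(np.clip(r, -1.0, 1.0))
            df = n - 2
            if abs(r) >= 1.0:
                p = 0.0
            else:
                t = r * np.sqrt(df / (1 - r**2))
                p = float(2 * stats.t.sf(abs(t), df))
            r_row.append(r)
            p_row.append(p)
        rows_r.append(r_row)
        rows_p.append(p_row)
    idx = [m.module_id for m in modules]
    r_frame = pd.DataFrame(rows_r, index=idx, columns=conditions)
    p_frame = pd.DataFrame(rows_p, index=idx, columns=conditions)
    q = multipletests(p_frame.to_numpy().ravel(), method="fdr_bh")[1].reshape(p_frame.shape)
    q_frame = pd.DataFrame(q, index=idx, columns=conditions)
    return r_frame, p_frame, q_frame


def tf_subnetwork_correlations(
    matrix: ExpressionMatrix,
    modules: list[GeneModule],
    module_ids: list[int],
    tf_list: list[str],
    r_min: float = 0.7,
) -> pd.DataFrame:
    """Pearson edges among transcription factors inside selected modules.

    Returns an edge table (tf_a, tf_b, r) with |r| >= r_min. TFs absent from
    the matrix are an error naming the missing ids; no TF inside the selected
    modules yields an empty table (with a warning).
    """
    if not tf_list:
        raise ValueError("tf_list must be non-empty")
    missing = [g for g in tf_list if g not in matrix.values.index]
    if missing:
        raise KeyError(f"TF id(s) not in expression matrix: {missing}")
    selected_genes: set[str] = set()
    for m in modules:
        if m.module_id in module_ids:
            selected_genes |= set(m.genes)
    tfs = sorted(g for g in tf_list if g in selected_genes)
    if not tfs:
        warnings.warn("no TFs found inside the selected modules")
        return pd.DataFrame(columns=["tf_a", "tf_b", "r"])
    arr = matrix.values.loc[tfs].to_numpy(dtype=float)
    r = np.corrcoef(arr)
    rows = []
    for i in range(len(tfs)):
        for j in range(i + 1, len(tfs)):
            if np.isfinite(r[i, j]) and abs(r[i, j]) >= r_min:
                rows.append({"tf_a": tfs[i], "tf_b": tfs[j], "r": float(r[i, j])})
    return pd.DataFrame(rows, columns=["tf_a", "tf_b", "r"])
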