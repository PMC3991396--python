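"""ARACNe-style reverse network engineering from expression profiles.

All-vs-all mutual information (MI, in nats) between gene pairs, a
permutation-null significance cutoff with Bonferroni control over the pair
family, data-processing-inequality (DPI) pruning of the weakest edge in
fully connected triplets, hub extraction by degree, and first-neighbor
subnetworks of the most highly expressed transcription factors among the
hubs.

The default MI estimator is the Gaussian copula: each profile is rank
transformed to normal scores, making the estimate invariant to monotone
marginal distortions, and MI is the closed form -0.5*ln(1 - rho^2) of the
normal-score correlation. An equal-frequency binned plug-in estimator is
available as a cross-check.
"""

from __future__ import annotations

import warnings
from math import ceil, comb

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix


def _normal_scores(x: np.ndarray) -> np.ndarray:
    n = x.size
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf(ranks / (n + 1))


def _copula_mi_from_rho(rho: float) -> float:
    rho = float(np.clip(rho, -0.999999, 0.999999))
    return max(0.0, -0.5 * np.log1p(-rho * rho))


def pairwise_mi(
    x: np.ndarray,
    y: np.ndarray,
    estimator: str = "gaussian_copula",
    n_bins: int | None = None,
) -> float:
    """Mutual information of two profiles in nats (non-negative, symmetric).

    ``gaussian_copula``: rank-transform then closed-form Gaussian MI —
    rank-invariant and fast. ``adaptive_bins``: equal-frequency binning
    (default ``ceil(sqrt(n/5))`` bins per axis) with the plug-in entropy
    estimate. A constant input vector carries no information: MI = 0.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("profiles must have equal length")
    if x.size < 10:
        raise ValueError("need >= 10 observations for an MI estimate")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant profile: MI set to 0")
        return 0.0
    if estimator == "gaussian_copula":
        rho = float(np.corrcoef(_normal_scores(x), _normal_scores(y))[0, 1])
        return _copula_mi_from_rho(rho)
    if estimator == "adaptive_bins":
        n = x.size
        b = n_bins or max(2, ceil(n ** (1.0 / 3.0)))
        qx = np.quantile(x, np.linspace(0, 1, b + 1)[1:-1])
        qy = np.quantile(y, np.linspace(0, 1, b + 1)[1:-1])
        ix = np.digitize(x, qx)
        iy = np.digitize(y, qy)
        joint = np.zeros((b, b))
        np.add.at(joint, (ix, iy), 1.0)
        joint /= n
        px = joint.sum(axis=1, keepdims=True)
        py = joint.sum(axis=0, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            terms = joint * np.log(joint / (px * py))
        mi = float(np.nansum(terms))
        # Miller-Madow bias correction for the plug-in estimate
        k_xy = int((joint > 0).sum())
        k_x = int((px > 0).sum())
        k_y = int((py > 0).sum())
        mi -= (k_xy - k_x - k_y + 1) / (2.0 * n)
        return max(0.0, mi)
    raise ValueError(f"unknown estimator {estimator!r}")


def mi_matrix(matrix: ExpressionMatrix, genes: list[str] | None = None) -> pd.DataFrame:
    """All-pairs Gaussian-copula MI, computed via one normal-score transform
    and a single correlation matrix."""
    values = matrix.values if genes is None else matrix.values.loc[list(genes)]
    arr = values.to_numpy(dtype=float)
    scores = np.apply_along_axis(_normal_scores, 1, arr)
    sd = arr.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.corrcoef(scores)
    rho = np.where(np.isfinite(rho), rho, 0.0)
    rho = np.clip(rho, -0.999999, 0.999999)
    mi = -0.5 * np.log1p(-rho * rho)
    mi[sd == 0, :] = 0.0
    mi[:, sd == 0] = 0.0
    np.fill_diagonal(mi, 0.0)  # self-MI is not a pairwise edge quantity
    return pd.DataFrame(mi, index=values.index, columns=values.index)


def mi_significance_threshold(
    matrix: ExpressionMatrix,
    alpha: float = 1e-7,
    n_null: int = 100_000,
    correction: str = "bonferroni",
    seed: int = 0,
    estimator: str = "gaussian_copula",
    tail_quantile: float = 0.99,
) -> tuple[float, dict]:
    """MI cutoff at significance ``alpha`` from a permutation null.

    Null MI values come from independently permuted profile pairs drawn from
    the matrix. Under Bonferroni correction the per-pair level is
    ``alpha / C(n_genes, 2)``. When the corrected quantile lies beyond the
    empirical null (the usual case for alpha = 1e-7), the null tail above
    ``tail_quantile`` is fit with an exponential and extrapolated; the fit
    diagnostics are returned alongside the cutoff.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if correction not in ("bonferroni", "none"):
        raise ValueError("correction must be 'bonferroni' or 'none'")
    n_pairs = comb(matrix.n_genes, 2)
    level = alpha / n_pairs if correction == "bonferroni" else alpha
    level = min(1.0, level)
    if level >= 1.0:
        return 0.0, {"method": "trivial", "level": level, "n_null": 0}

    rng = np.random.default_rng(seed)
    arr = matrix.values.to_numpy(dtype=float)
    n_g, n_s = arr.shape
    if estimator == "gaussian_copula":
        # vectorized: permuting a profile permutes its normal scores
        scores = np.apply_along_axis(_normal_scores, 1, arr)
        scores = (scores - scores.mean(axis=1, keepdims=True))
        norms = np.linalg.norm(scores, axis=1)
        norms = np.where(norms == 0, 1.0, norms)
        scores /= norms[:, None]
        gi = rng.integers(0, n_g, size=n_null)
        gj = rng.integers(0, n_g, size=n_null)
        perms = np.argsort(rng.random((n_null, n_s)), axis=1)
        rho = np.einsum("ij,ij->i", scores[gi], np.take_along_axis(scores[gj], perms, axis=1))
        null = -0.5 * np.log1p(-np.clip(rho, -0.999999, 0.999999) ** 2)
    else:
        null = np.empty(n_null)
        for i in range(n_null):
            g1, g2 = rng.integers(0, n_g, size=2)
            null[i] = pairwise_mi(arr[g1], arr[g2, rng.permutation(n_s)], estimator=estimator)
    null = np.sort(null)
    info: dict = {"method": "empirical", "level": level, "n_null": n_null}
    if level >= 1.0 / n_null:
        cutoff = float(np.quantile(null, 1.0 - level))
    else:
        # exponential tail fit: P(MI > m) ~ tail0 * exp(-(m - m0)/scale)
        m0 = float(np.quantile(null, tail_quantile))
        tail = null[null > m0] - m0
        if tail.size < 10:
            raise ValueError("null sample too small for tail extrapolation; raise n_null")
        scale = float(tail.mean())
        tail0 = tail.size / n_null
        cutoff = m0 + scale * np.log(tail0 / level)
        info.update(
            {
                "method": "exponential_tail",
                "tail_quantile": tail_quantile,
                "tail_start": m0,
                "tail_scale": scale,
                "tail_mass": tail0,
                "tail_n": int(tail.size),
            }
        )
    return float(cutoff), info


def all_vs_all(
    matrix: ExpressionMatrix,
    genes: list[str] | None = None,
    cutoff: float = 0.0,
    max_genes: int = 20_000,
    force: bool = False,
) -> nx.Graph:
    """MI network: an edge for every gene pair with MI >= cutoff.

    Edge attribute ``mi`` holds the estimate in nats. Refuses more than
    ``max_genes`` genes unless ``force`` (desk-scale guard).
    """
    gene_list = list(genes) if genes is not None else matrix.genes
    if len(gene_list) < 3:
        raise ValueError("need >= 3 genes for a network")
    if len(gene_list) > max_genes and not force:
        raise ValueError(f"{len(gene_list)} genes exceeds the desk-scale guard ({max_genes}); pass force=True")
    mi = mi_matrix(matrix, gene_list)
    arr = mi.to_numpy()
    graph = nx.Graph()
    graph.add_nodes_from(gene_list)
    iu, ju = np.triu_indices(len(gene_list), k=1)
    keep = arr[iu, ju] >= cutoff
    for i, j in zip(iu[keep], ju[keep]):
        graph.add_edge(gene_list[i], gene_list[j], mi=float(arr[i, j]))
    return graph


def dpi_prune(network: nx.Graph, tolerance: float = 0.1) -> nx.Graph:
    """Data-processing-inequality pruning of fully connected triplets.

    For every triangle (i, j, k) in the *input* network, the weakest of the
    three MI edges is marked for removal when its MI is below
    ``(1 - tolerance) * min(other two)``; all removals are applied
    simultaneously to a copy.
    """
    if not (0.0 <= tolerance < 1.0):
        raise ValueError("tolerance must lie in [0, 1)")
    doomed: set[frozenset] = set()
    adj = network.adj
    nodes = list(network.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    for a in nodes:
        nbrs_a = [x for x in adj[a] if index[x] > index[a]]
        for b in nbrs_a:
            for c in set(nbrs_a) & set(adj[b]):
                if index[c] <= index[b]:
                    continue
                trip = [
                    (frozenset((a, b)), adj[a][b]["mi"]),
                    (frozenset((a, c)), adj[a][c]["mi"]),
                    (frozenset((b, c)), adj[b][c]["mi"]),
                ]
                trip.sort(key=lambda t: t[1])
                weakest_edge, weakest = trip[0]
                second = trip[1][1]
                if weakest < (1.0 - tolerance) * second:
                    doomed.add(weakest_edge)
    pruned = network.copy()
    pruned.remove_edges_from(tuple(e) for e in doomed)
    return pruned


def degree_table(network: nx.Graph) -> pd.DataFrame:
    deg = dict(network.degree())
    table = pd.DataFrame({"gene": list(deg), "degree": list(deg.values())})
    table = table.sort_values(["degree", "gene"], ascending=[False, True], kind="stable")
    return table.reset_index(drop=True)


def extract_hubs(network: nx.Graph, fraction: float = 0.1) -> tuple[list[str], dict]:
    """Top-degree hub genes: the top ``fraction`` of nodes with >= 1 edge.

    Nodes are ranked by degree (descending, gene-id tie-break); the top
    ``ceil(fraction * n_connected)`` are hubs. Also reports the number of
    interactions the hubs collectively participate in (edges incident to at
    least one hub) and the network's average degree over connected nodes and
    over all nodes.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must lie in (0, 1]")
    if network.number_of_nodes() == 0:
        raise ValueError("empty network")
    table = degree_table(network)
    connected = table[table["degree"] > 0]
    if len(connected) == 0:
        raise ValueError("network has no edges")
    n_hubs = ceil(fraction * len(connected))
    hubs = connected["gene"].head(n_hubs).tolist()
    hub_set = set(hubs)
    hub_edges = sum(1 for u, v in network.edges if u in hub_set or v in hub_set)
    n_edges = network.number_of_edges()
    stats_ = {
        "n_nodes": network.number_of_nodes(),
        "n_connected": int(len(connected)),
        "n_edges": n_edges,
        "n_hubs": n_hubs,
        "hub_interactions": hub_edges,
        "avg_degree_connected": 2 * n_edges / len(connected),
        "avg_degree_all": 2 * n_edges / network.number_of_nodes(),
    }
    return hubs, stats_


def tf_neighborhoods(
    network: nx.Graph,
    tf_list: list[str],
    matrix: ExpressionMatrix,
    top_k: int = 5,
    hub_fraction: float = 0.1,
    cluster_of: dict[str, int] | None = None,
) -> dict[str, nx.Graph]:
    """First-neighbor subnetworks of the most expressed TFs among the hubs.

    TFs present among the network hubs are ranked by mean expression across
    all samples; the ``top_k`` get a subnetwork of themselves plus first
    neighbors. Node attribute ``mean_expr`` carries the overall mean log2
    expression; with ``cluster_of`` (condition -> cluster id) per-cluster
    means are attached as ``mean_expr_c<id>``.
    """
    if not tf_list:
        raise ValueError("tf_list must be non-empty")
    hubs, _ = extract_hubs(network, fraction=hub_fraction)
    tf_hubs = [g for g in tf_list if g in set(hubs)]
    if not tf_hubs:
        warnings.warn("no TFs among the network hubs")
        return {}
    mean_expr = matrix.values.mean(axis=1)
    tf_hubs.sort(key=lambda g: (-float(mean_expr.get(g, -np.inf)), g))
    chosen = tf_hubs[:top_k]

    cluster_means = None
    if cluster_of is not None:
        by_cluster: dict[int, list[str]] = {}
        for cond, cl in cluster_of.items():
            by_cluster.setdefault(cl, []).extend(matrix.samples_of(cond))
        cluster_means = {cl: matrix.values[cols].mean(axis=1) for cl, cols in by_cluster.items() if cols}

    out = {}
    for tf in chosen:
        nodes = [tf] + sorted(network.neighbors(tf)) if tf in network else [tf]
        sub = network.subgraph(nodes).copy() if tf in network else nx.Graph()
        if tf not in sub:
            sub.add_node(tf)
        for g in sub.nodes:
            sub.nodes[g]["mean_expr"] = float(mean_expr.get(g, np.nan))
            sub.nodes[g]["is_tf"] = g in set(tf_list)
            if cluster_means:
                for cl, cm in cluster_means.items():
                    sub.nodes[g][f"mean_expr_c{cl}"] = float(cm.get(g, np.nan))
        out[tf] = sub
    return out
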