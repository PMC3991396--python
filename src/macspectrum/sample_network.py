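"""Coregulation analysis (CRA): sample-sample Pearson graphs, Markov
clustering, and a 3-D force-directed layout.

The sample graph connects two arrays when the Pearson correlation of their
expression profiles (over a chosen gene set) clears a threshold; Markov
clustering partitions it and a Fruchterman-Reingold layout embeds it in 3-D.
The layout coordinates are the raw material of the activation-spectrum
vectors, so they are *not* rescaled after the force simulation — distances
keep their equilibrium meaning.
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np

from .containers import ExpressionMatrix


def correlation_graph(
    matrix: ExpressionMatrix,
    genes: list[str] | None = None,
    r_threshold: float = 0.85,
) -> nx.Graph:
    """Sample-sample Pearson graph over the given gene set.

    Edge (s, t) exists iff Pearson r of the two sample profiles >= threshold;
    the r value is stored as edge attribute ``weight``. Samples whose profile
    has zero variance are dropped with a warning and listed in the graph's
    ``excluded`` attribute.
    """
    if not (0.0 < r_threshold < 1.0):
        raise ValueError("r_threshold must lie in (0, 1)")
    if matrix.n_samples < 3:
        raise ValueError("need >= 3 samples for a sample graph")
    sub = matrix.values if genes is None else matrix.values.loc[list(genes)]
    if sub.shape[0] == 0:
        raise ValueError("gene list is empty")
    arr = sub.to_numpy(dtype=float)
    sd = arr.std(axis=0)
    keep = sd > 0
    excluded = [s for s, k in zip(matrix.samples, keep) if not k]
    if excluded:
        warnings.warn(f"excluding zero-variance sample profile(s): {excluded}")
    samples = [s for s, k in zip(matrix.samples, keep) if k]
    r = np.corrcoef(arr[:, keep], rowvar=False)

    graph = nx.Graph(r_threshold=r_threshold, excluded=excluded)
    graph.add_nodes_from(samples)
    for i in range(len(samples)):
        for j in range(i + 1, len(samples)):
            if r[i, j] >= r_threshold:
                graph.add_edge(samples[i], samples[j], weight=float(r[i, j]))
    return graph


def mcl_cluster(
    graph: nx.Graph,
    inflation: float = 2.0,
    tol: float = 1e-8,
    max_iter: int = 200,
    self_loops: float = 1.0,
) -> dict[str, int]:
    """Markov clustering of a weighted graph.

    Alternates expansion (squaring the column-stochastic transition matrix)
    and inflation (entrywise power then column renormalization) until the
    matrix changes by less than ``tol`` or ``max_iter`` is reached. Rows with
    mass on their own column (attractors) seed the clusters; each node joins
    the cluster of the attractor(s) holding its column mass. Deterministic.
    """
    if inflation <= 1:
        raise ValueError("inflation must be > 1")
    nodes = list(graph.nodes)
    if not nodes:
        return {}
    n = len(nodes)
    m = nx.to_numpy_array(graph, nodelist=nodes, weight="weight")
    np.fill_diagonal(m, self_loops)
    m = m / m.sum(axis=0, keepdims=True)
    for _ in range(max_iter):
        expanded = m @ m
        inflated = expanded**inflation
        inflated /= inflated.sum(axis=0, keepdims=True)
        if np.abs(inflated - m).max() < tol:
            m = inflated
            break
        m = inflated
    # attractors: nodes with non-negligible mass on their own row
    thresh = 1e-6
    attractors = [i for i in range(n) if m[i, i] > thresh]
    labels: dict[str, int] = {}
    # union attractors that share a column (overlapping clusters merge)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    for j in range(n):
        owners = [i for i in attractors if m[i, j] > thresh]
        for a, b in zip(owners, owners[1:]):
            union(a, b)
    cluster_of_root: dict[int, int] = {}
    for j in range(n):
        owners = [i for i in attractors if m[i, j] > thresh]
        root = find(owners[0]) if owners else find(j)
        if root not in cluster_of_root:
            cluster_of_root[root] = len(cluster_of_root)
        labels[nodes[j]] = cluster_of_root[root]
    return labels


def layout_3d(
    graph: nx.Graph,
    iterations: int = 500,
    seed: int = 0,
    k: float | None = None,
) -> dict[str, np.ndarray]:
    """3-D Fruchterman-Reingold layout with correlation-weighted attraction.

    ``k`` is the natural spring length (default ``1/sqrt(n)``); attraction of
    an edge scales with its ``weight``; cooling is linear. Coordinates are
    centered on their centroid but never rescaled, so pairwise distances keep
    the equilibrium geometry (a lone edge settles near length ``k``).
    Isolated nodes feel repulsion only and drift to an outer shell.
    """
    nodes = list(graph.nodes)
    n = len(nodes)
    if n == 0:
        raise ValueError("graph is empty")
    rng = np.random.default_rng(seed)
    pos = rng.uniform(-0.5, 0.5, size=(n, 3))
    if n == 1:
        return {nodes[0]: np.zeros(3)}
    if k is None:
        k = 1.0 / np.sqrt(n)
    index = {v: i for i, v in enumerate(nodes)}
    if graph.number_of_edges():
        eu, ev, ew = zip(*[(index[u], index[v], d.get("weight", 1.0)) for u, v, d in graph.edges(data=True)])
        eu, ev = np.array(eu), np.array(ev)
        ew = np.array(ew, dtype=float)
    else:
        eu = ev = np.array([], dtype=int)
        ew = np.array([])
    t0 = 0.1 * max(1.0, np.ptp(pos))
    for it in range(iterations):
        delta = pos[:, None, :] - pos[None, :, :]
        dist = np.linalg.norm(delta, axis=-1)
        np.fill_diagonal(dist, np.inf)
        # repulsion k^2/d between every pair
        force = (k * k / dist**2)[:, :, None] * delta
        disp = force.sum(axis=1)
        if eu.size:
            dvec = pos[eu] - pos[ev]
            d = np.linalg.norm(dvec, axis=1)
            d = np.where(d == 0, 1e-9, d)
            # attraction d^2/k along each edge, scaled by correlation weight
            f = (ew * d / k)[:, None] * dvec
            np.subtract.at(disp, eu, f)
            np.add.at(disp, ev, f)
        temp = t0 * (1.0 - it / iterations)
        length = np.linalg.norm(disp, axis=1)
        length = np.where(length == 0, 1e-9, length)
        pos += disp / length[:, None] * np.minimum(length, temp)[:, None]
    pos -= pos.mean(axis=0)
    return {v: pos[i].copy() for v, i in index.items()}
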