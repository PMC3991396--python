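"""Gene-set enrichment analysis with coexpression modules as gene sets, and
hypergeometric over-representation analysis.

GSEA follows the weighted Kolmogorov-Smirnov formulation: genes are ranked
by a two-group metric (signal-to-noise by default), a running sum earns
|score|^p-weighted increments at gene-set hits and uniform decrements at
misses, and the enrichment score (ES) is the running-sum extremum. ES is
normalized against a permutation null (phenotype-label permutations when the
design is large enough, gene-set permutations otherwise) to give NES, a
nominal p, and a normalized-tail FDR q. Over-representation analysis is a
plain hypergeometric upper-tail test with BH correction — the generic
stand-in for GO enrichment given a user-supplied term-to-gene annotation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix


def _signal2noise(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """GSEA signal-to-noise: (mu_a - mu_b) / (sd_a + sd_b), each sd floored
    at 0.2 * |mu| of its group (0.2 when the mean is zero)."""
    mu_a, mu_b = a.mean(axis=1), b.mean(axis=1)
    sd_a, sd_b = a.std(axis=1, ddof=1), b.std(axis=1, ddof=1)
    floor_a = np.where(mu_a == 0, 0.2, 0.2 * np.abs(mu_a))
    floor_b = np.where(mu_b == 0, 0.2, 0.2 * np.abs(mu_b))
    sd_a = np.maximum(sd_a, floor_a)
    sd_b = np.maximum(sd_b, floor_b)
    return (mu_a - mu_b) / (sd_a + sd_b)


def _tstat(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        t, _ = stats.ttest_ind(a, b, axis=1, equal_var=False)
    return np.where(np.isfinite(t), t, 0.0)


_METRICS = {"signal2noise": _signal2noise, "tstat": _tstat}


def rank_genes(
    matrix: ExpressionMatrix,
    group_a: str,
    group_b: str,
    metric: str = "signal2noise",
) -> pd.Series:
    """Rank all genes by a two-group differential metric, descending.

    Ties are broken by gene-id lexicographic order so rankings are
    deterministic. signal2noise requires >= 3 samples per group.
    """
    if metric not in _METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {sorted(_METRICS)}")
    a_cols = matrix.samples_of(group_a)
    b_cols = matrix.samples_of(group_b)
    min_n = 3 if metric == "signal2noise" else 2
    for name, cols in ((group_a, a_cols), (group_b, b_cols)):
        if len(cols) < min_n:
            raise ValueError(f"group {name!r} has {len(cols)} samples; {metric} needs >= {min_n}")
    scores = _METRICS[metric](matrix.values[a_cols].to_numpy(), matrix.values[b_cols].to_numpy())
    genes = np.asarray(matrix.genes, dtype=object)
    order = np.lexsort((genes, -scores))
    return pd.Series(scores[order], index=genes[order], name=metric)


@dataclass
class ESResult:
    es: float
    running_sum: np.ndarray
    leading_edge: list[str]
    hit_positions: np.ndarray


def enrichment_score(ranked: pd.Series, gene_set, weight: float = 1.0) -> ESResult:
    """Weighted KS running-sum enrichment score on a descending ranking.

    Hits increment by |score|^weight (normalized over hits); misses decrement
    by 1/(N - Nh). ES is the extremum of the running sum by absolute value
    (earliest extremum on ties); the leading edge is the hits before the
    positive peak, or after the negative trough. A gene set covering the
    whole ranking is degenerate (no misses) and rejected.
    """
    genes = ranked.index.to_numpy(dtype=object)
    hit = np.isin(genes, list(gene_set))
    n, nh = len(genes), int(hit.sum())
    if nh == 0:
        raise ValueError("gene set has empty intersection with the ranking")
    if nh == n:
        raise ValueError("gene set covers the entire ranking; miss weight undefined")
    w = np.abs(ranked.to_numpy(dtype=float)) ** weight
    hw = np.where(hit, w, 0.0)
    total = hw.sum()
    if total == 0:  # all hit scores are exactly zero: fall back to uniform
        hw = hit.astype(float)
        total = float(nh)
    steps = hw / total - (~hit) / (n - nh)
    running = np.cumsum(steps)
    i_ext = int(np.argmax(np.abs(running)))
    es = float(running[i_ext])
    if es >= 0:
        leading = [g for g, h in zip(genes[: i_ext + 1], hit[: i_ext + 1]) if h]
    else:
        leading = [g for g, h in zip(genes[i_ext:], hit[i_ext:]) if h]
    return ESResult(es, running, leading, np.flatnonzero(hit))


def _es_only(scores: np.ndarray, hit: np.ndarray, weight: float) -> float:
    """Fast ES for permutation loops: scores already in rank order."""
    n = scores.size
    nh = int(hit.sum())
    w = np.abs(scores) ** weight
    hw = np.where(hit, w, 0.0)
    total = hw.sum()
    if total == 0:
        hw = hit.astype(float)
        total = float(nh)
    running = np.cumsum(hw / total - (~hit) / (n - nh))
    return float(running[np.argmax(np.abs(running))])


def gsea_permutation(
    matrix: ExpressionMatrix,
    group_a: str,
    group_b: str,
    gene_sets: dict[str, list[str]],
    n_perm: int = 1000,
    mode: str = "phenotype",
    seed: int = 0,
    metric: str = "signal2noise",
    weight: float = 1.0,
) -> pd.DataFrame:
    """GSEA with permutation-based NES, nominal p, and normalized-tail FDR q.

    Phenotype mode permutes group labels and recomputes the ranking metric;
    when the requested ``n_perm`` reaches the number of distinct label
    assignments the null is enumerated exhaustively (``exact`` column True).
    Designs with fewer than 7 samples fall back to gene-set permutation with
    a warning. NES divides ES by the mean |permuted ES| of matching sign;
    nominal p is the matching-sign tail fraction; q follows the GSEA
    convention (ratio of permuted to observed normalized tail fractions,
    clipped at 1).
    """
    if mode not in ("phenotype", "geneset"):
        raise ValueError("mode must be 'phenotype' or 'geneset'")
    if n_perm < 100:
        warnings.warn("n_perm < 100: reported q-values will be unstable")
    a_cols = matrix.samples_of(group_a)
    b_cols = matrix.samples_of(group_b)
    if mode == "phenotype" and len(a_cols) + len(b_cols) < 7:
        # small designs: exhaustive enumeration is still well-defined, but a
        # sampled phenotype null would be too coarse — fall back to gene sets
        if n_perm < comb(len(a_cols) + len(b_cols), len(a_cols)):
            warnings.warn("fewer than 7 samples and non-exhaustive n_perm: switching to gene-set permutation")
            mode = "geneset"

    ranked = rank_genes(matrix, group_a, group_b, metric=metric)
    names = list(gene_sets)
    genes_in_rank = set(ranked.index)
    for nm in names:
        if not genes_in_rank & set(gene_sets[nm]):
            raise ValueError(f"gene set {nm!r} has no genes in the ranking")
    obs = {nm: enrichment_score(ranked, gene_sets[nm], weight=weight) for nm in names}

    rng = np.random.default_rng(seed)
    genes = np.asarray(matrix.genes, dtype=object)
    exact = False
    perm_es = {nm: [] for nm in names}
    if mode == "phenotype":
        cols = a_cols + b_cols
        arr = matrix.values[cols].to_numpy(dtype=float)
        na = len(a_cols)
        n_all = len(cols)
        n_distinct = comb(n_all, na)
        if n_perm >= n_distinct:
            assignments = list(combinations(range(n_all), na))
            exact = True
        else:
            assignments = []
            for _ in range(n_perm):
                assignments.append(tuple(rng.choice(n_all, size=na, replace=False)))
        member = {nm: np.isin(genes, list(gene_sets[nm])) for nm in names}
        fn = _METRICS[metric]
        for idx_a in assignments:
            sel = np.zeros(n_all, dtype=bool)
            sel[list(idx_a)] = True
            scores = fn(arr[:, sel], arr[:, ~sel])
            order = np.lexsort((genes, -scores))
            s_sorted = scores[order]
            for nm in names:
                perm_es[nm].append(_es_only(s_sorted, member[nm][order], weight))
    else:
        s_sorted = ranked.to_numpy(dtype=float)
        n = s_sorted.size
        sizes = {nm: int(np.isin(ranked.index.to_numpy(dtype=object), list(gene_sets[nm])).sum()) for nm in names}
        for nm in names:
            sz = sizes[nm]
            for _ in range(n_perm):
                hit = np.zeros(n, dtype=bool)
                hit[rng.choice(n, size=sz, replace=False)] = True
                perm_es[nm].append(_es_only(s_sorted, hit, weight))

    rows = []
    all_nes_perm: list[float] = []
    nes_obs: dict[str, float] = {}
    for nm in names:
        es = obs[nm].es
        null = np.asarray(perm_es[nm], dtype=float)
        pos_mean = null[null > 0].mean() if (null > 0).any() else np.nan
        neg_mean = np.abs(null[null < 0]).mean() if (null < 0).any() else np.nan
        denom = pos_mean if es >= 0 else neg_mean
        nes = es / denom if np.isfinite(denom) and denom > 0 else np.nan
        nes_obs[nm] = nes
        same = null[null >= 0] if es >= 0 else null[null < 0]
        if same.size:
            k = int((np.abs(same) >= abs(es)).sum())
            if exact:
                # exhaustive null already contains the observed assignment
                p = k / same.size
            else:
                # sampled null: add-one permutation convention (unbiased)
                p = (1 + k) / (1 + same.size)
        else:
            p = 1.0
        with np.errstate(invalid="ignore", divide="ignore"):
            nes_null = np.where(null >= 0, null / pos_mean, null / neg_mean)
        all_nes_perm.extend(nes_null[np.isfinite(nes_null)].tolist())
        rows.append({"gene_set": nm, "es": es, "nes": nes, "p": p,
                     "n_hits": len(obs[nm].hit_positions),
                     "leading_edge": "|".join(map(str, obs[nm].leading_edge))})

    nes_perm_arr = np.asarray(all_nes_perm, dtype=float)
    nes_obs_arr = np.asarray([nes_obs[nm] for nm in names], dtype=float)
    qs = []
    for nm in names:
        nes = nes_obs[nm]
        if not np.isfinite(nes):
            qs.append(np.nan)
            continue
        if nes >= 0:
            num_pool = nes_perm_arr[nes_perm_arr >= 0]
            obs_pool = nes_obs_arr[np.isfinite(nes_obs_arr) & (nes_obs_arr >= 0)]
            num = (num_pool >= nes).mean() if num_pool.size else 0.0
            den = (obs_pool >= nes).mean() if obs_pool.size else 1.0
        else:
            num_pool = nes_perm_arr[nes_perm_arr < 0]
            obs_pool = nes_obs_arr[np.isfinite(nes_obs_arr) & (nes_obs_arr < 0)]
            num = (num_pool <= nes).mean() if num_pool.size else 0.0
            den = (obs_pool <= nes).mean() if obs_pool.size else 1.0
        qs.append(min(1.0, num / den) if den > 0 else np.nan)

    table = pd.DataFrame(rows)
    table["q"] = qs
    table["exact"] = exact
    table["mode"] = mode
    table["n_perm"] = len(next(iter(perm_es.values()))) if names else 0
    return table.sort_values("nes", ascending=False, kind="stable").reset_index(drop=True)


def volcano_table(results: pd.DataFrame, nes_min: float = 1.0, p_max: float = 0.05) -> pd.DataFrame:
    """Flag gene sets enriched (NES > nes_min, p < p_max) or depleted
    (NES < -nes_min, p < p_max)."""
    out = results.copy()
    out["enriched"] = (out["nes"] > nes_min) & (out["p"] < p_max)
    out["depleted"] = (out["nes"] < -nes_min) & (out["p"] < p_max)
    return out


def ora_hypergeometric(
    query: set[str] | list[str],
    universe: set[str] | list[str],
    annotation: dict[str, set[str] | list[str]],
) -> pd.DataFrame:
    """Hypergeometric upper-tail over-representation of each term's gene set.

    For a universe of N genes, a term with K universe genes, and a query of
    n genes with k overlapping, p = P(X >= k) under Hypergeom(N, K, n). Terms
    with no universe genes are skipped (with a note column absent from the
    output); BH correction is over the tested terms.
    """
    query = set(query)
    universe = set(universe)
    if not query:
        raise ValueError("query gene set is empty")
    stray = query - universe
    if stray:
        raise ValueError(f"query gene(s) outside the universe: {sorted(stray)[:10]}")
    n_universe, n_query = len(universe), len(query)
    rows = []
    for term in sorted(annotation):
        term_genes = set(annotation[term]) & universe
        if not term_genes:
            warnings.warn(f"term {term!r} has no genes in the universe; skipped")
            continue
        k = len(query & term_genes)
        big_k = len(term_genes)
        p = float(stats.hypergeom.sf(k - 1, n_universe, big_k, n_query))
        rows.append(
            {
                "term": term,
                "overlap": k,
                "term_size": big_k,
                "expected": big_k * n_query / n_universe,
                "p": min(1.0, p),
            }
        )
    table = pd.DataFrame(rows, columns=["term", "overlap", "term_size", "expected", "p"])
    if len(table):
        table["q"] = multipletests(table["p"].to_numpy(), method="fdr_bh")[1]
    else:
        table["q"] = []
    return table
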