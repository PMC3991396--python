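"""Normalization, detection filtering, variance ranking, and DE screening.

The upstream contract for microarray log2 intensities: quantile-normalize
across arrays, call a gene "expressed" if its condition mean clears the
empirical background in at least one stimulation condition, rank genes by
variance for the condition-correlation analyses, and screen differential
expression with Welch tests / one-way ANOVA under Benjamini-Hochberg FDR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample column onto the mean-of-sorted reference distribution.

    After normalization each column's sorted values equal the row-wise mean of
    the input's sorted columns. Ties within a column are resolved by ordinal
    rank (column position), which makes the operation exactly idempotent.
    """
    arr = matrix.values.to_numpy(dtype=float)
    if not np.isfinite(arr).all():
        raise ValueError("missing/non-finite values: impute upstream before normalization")
    if arr.shape[1] < 2:
        raise ValueError("quantile normalization needs >= 2 samples")
    order = np.argsort(arr, axis=0, kind="stable")
    reference = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        out[order[:, j], j] = reference
    frame = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    return ExpressionMatrix(frame, matrix.design.copy())


@dataclass
class DetectionResult:
    """Per-condition detection calls and the union 'expressed' gene set."""

    expressed_genes: list[str]
    calls: pd.DataFrame  # genes x conditions, boolean
    background: float  # the background level used (log2)


def detection_filter(
    matrix: ExpressionMatrix,
    background_quantile: float = 0.25,
    min_margin: float = 0.5,
) -> DetectionResult:
    """Call a gene expressed in a condition if its condition-mean exceeds the
    empirical background (a quantile of all intensities) by ``min_margin``.

    The expressed set is the union over conditions — present in at least one
    stimulation condition.
    """
    if not (0.0 < background_quantile < 1.0):
        raise ValueError("background_quantile must lie in (0, 1)")
    for c in matrix.conditions:
        if len(matrix.samples_of(c)) == 0:
            raise ValueError(f"condition {c!r} has no samples")
    background = float(np.quantile(matrix.values.to_numpy(), background_quantile))
    means = matrix.condition_means()
    calls = means > (background + min_margin)
    expressed = list(calls.index[calls.any(axis=1)])
    return DetectionResult(expressed, calls, background)


def top_variable_genes(matrix: ExpressionMatrix, n: int) -> list[str]:
    """The ``n`` genes with largest across-sample variance; ties broken by
    gene-id lexicographic order for determinism."""
    if n <= 0:
        raise ValueError("n must be positive")
    if n > matrix.n_genes:
        raise ValueError(f"requested {n} genes but matrix has {matrix.n_genes}")
    var = matrix.values.var(axis=1, ddof=1)
    order = sorted(var.index, key=lambda g: (-var[g], str(g)))
    return order[:n]


def _bh_adjust(pvals: np.ndarray) -> np.ndarray:
    return multipletests(pvals, method="fdr_bh")[1]


def differential_expression(
    matrix: ExpressionMatrix,
    group_a: str,
    group_b: str,
    fc_min: float = 2.0,
    q_max: float = 0.05,
) -> pd.DataFrame:
    """Per-gene Welch t-test of ``group_a`` vs ``group_b`` on log2 values.

    Fold change is ``2**(mean_a - mean_b)`` (difference of log2 means, never a
    ratio of raw means). Returns a table with columns
    ``log2fc, fc, p, q, pass`` where ``pass`` means ``|log2fc| > log2(fc_min)``
    and ``q < q_max``. Genes with zero variance in both groups get p = 1.
    """
    a_cols = matrix.samples_of(group_a)
    b_cols = matrix.samples_of(group_b)
    for name, cols in ((group_a, a_cols), (group_b, b_cols)):
        if len(cols) < 2:
            raise ValueError(f"group {name!r} has {len(cols)} sample(s); need >= 2 for a variance estimate")
    a = matrix.values[a_cols].to_numpy()
    b = matrix.values[b_cols].to_numpy()
    log2fc = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    degenerate = ~np.isfinite(p)
    p = np.where(degenerate, 1.0, p)
    q = _bh_adjust(p)
    table = pd.DataFrame(
        {
            "log2fc": log2fc,
            "fc": np.exp2(log2fc),
            "p": p,
            "q": q,
            "pass": (np.abs(log2fc) > np.log2(fc_min)) & (q < q_max),
            "degenerate": degenerate,
        },
        index=matrix.values.index,
    )
    return table


def anova_screen(matrix: ExpressionMatrix, q_max: float = 0.05) -> pd.DataFrame:
    """One-way (equal-variance) F-test per gene across condition groups.

    Vectorized classic ANOVA; constant genes (zero within- and between-group
    variance) are reported non-significant (p = 1) with a ``degenerate`` flag.
    Returns columns ``F, p, q, pass, degenerate``.
    """
    groups = [matrix.samples_of(c) for c in matrix.conditions]
    if len(groups) < 2:
        raise ValueError("ANOVA screen needs >= 2 conditions")
    for c, g in zip(matrix.conditions, groups):
        if len(g) < 2:
            raise ValueError(f"condition {c!r} has fewer than 2 samples")
    arr = matrix.values.to_numpy()
    n_total = arr.shape[1]
    k = len(groups)
    grand = arr.mean(axis=1)
    ss_between = np.zeros(arr.shape[0])
    ss_within = np.zeros(arr.shape[0])
    for cols in groups:
        idx = [matrix.samples.index(s) for s in cols]
        sub = arr[:, idx]
        gm = sub.mean(axis=1)
        ss_between += len(idx) * (gm - grand) ** 2
        ss_within += ((sub - gm[:, None]) ** 2).sum(axis=1)
    df_b, df_w = k - 1, n_total - k
    with np.errstate(invalid="ignore", divide="ignore"):
        f = (ss_between / df_b) / (ss_within / df_w)
        p = stats.f.sf(f, df_b, df_w)
    degenerate = ~np.isfinite(f)
    p = np.where(degenerate, 1.0, p)
    f = np.where(degenerate, 0.0, f)
    q = _bh_adjust(p)
    return pd.DataFrame(
        {"F": f, "p": p, "q": q, "pass": q < q_max, "degenerate": degenerate},
        index=matrix.values.index,
    )
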