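import numpy as np
import pandas as pd
import pytest

from macspectrum.containers import ExpressionMatrix
from macspectrum.synthetic import (
    demo_dataset,
    make_design,
    module_recovery_structure,
    simulate_expression,
)


@pytest.fixture(scope="session")
def demo():
    """Bundled demo dataset: 200 genes x 60 samples, 6 conditions."""
    matrix, structure = demo_dataset(seed=7)
    return matrix, structure


@pytest.fixture(scope="session")
def module_fixture():
    """Six planted 50-gene modules (effect/noise = 4) over 6 conditions."""
    design = make_design(6, 10, "Mb", seed=0)
    structure = module_recovery_structure(design, n_modules=6, module_size=50)
    matrix = simulate_expression(design, structure, n_background_genes=50, seed=0)
    return matrix, structure


@pytest.fixture()
def tiny_matrix():
    """Hand-sized matrix: 4 genes x 4 samples, 2 conditions."""
    design = pd.DataFrame(
        {
            "condition": ["base", "base", "stim", "stim"],
            "time_h": 72.0,
            "donor": ["d1", "d2", "d1", "d2"],
            "is_baseline": [True, True, False, False],
        },
        index=pd.Index(["s1", "s2", "s3", "s4"], name="sample_id"),
    )
    values = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0], [2.0, 1.0, 4.0, 3.0], [5.0, 5.0, 1.0, 1.0], [0.0, 0.5, 0.2, 0.4]],
        index=["g1", "g2", "g3", "g4"],
        columns=design.index,
    )
    return ExpressionMatrix(values, design)


def bh_brute(pvals):
    """Independent Benjamini-Hochberg oracle: sorted p*m/rank with a running
    minimum from the bottom."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = p[order] * m / np.arange(1, m + 1)
    for i in range(m - 2, -1, -1):
        adj[i] = min(adj[i], adj[i + 1])
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def es_brute(ranked, gene_set, weight=1.0):
    """Independent running-sum GSEA oracle (plain Python loop)."""
    genes = list(ranked.index)
    scores = list(ranked.to_numpy(dtype=float))
    hits = [g in set(gene_set) for g in genes]
    n, nh = len(genes), sum(hits)
    nr = sum(abs(s) ** weight for s, h in zip(scores, hits) if h)
    run, best = 0.0, 0.0
    for s, h in zip(scores, hits):
        if h:
            run += (abs(s) ** weight) / nr if nr > 0 else 1.0 / nh
        else:
            run -= 1.0 / (n - nh)
        if abs(run) > abs(best):
            best = run
    return best
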