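"""GSEA machinery against brute-force oracles: hand-checked signal-to-noise,
running-sum enrichment scores, exhaustive phenotype permutation on a 3v3
design, and exact hypergeometric over-representation."""

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from macspectrum.enrichment import (
    enrichment_score,
    gsea_permutation,
    ora_hypergeometric,
    rank_genes,
    volcano_table,
    _signal2noise,
)
from macspectrum.synthetic import make_design, module_recovery_structure, simulate_expression

from conftest import es_brute


class TestRankGenes:
    def test_signal2noise_hand_arithmetic(self):
        # group a: [4, 6] -> mu 5, sd sqrt(2); floored at max(sqrt(2), 1.0)
        # group b: [1, 3] -> mu 2, sd sqrt(2); floored at max(sqrt(2), 0.4)
        a = np.array([[4.0, 6.0]])
        b = np.array([[1.0, 3.0]])
        s = _signal2noise(a, b)[0]
        sd = np.sqrt(2)
        assert s == pytest.approx((5 - 2) / (sd + sd))
        # tight values hit the 0.2*|mu| floor
        a = np.array([[10.0, 10.001]])
        b = np.array([[5.0, 5.001]])
        s = _signal2noise(a, b)[0]
        assert s == pytest.approx((10.0005 - 5.0005) / (0.2 * 10.0005 + 0.2 * 5.0005))

    def test_planted_up_gene_ranks_first(self):
        design = make_design(2, 5, "Mb", seed=1)
        cond = design["condition"].unique()[1]
        st_ = module_recovery_structure(design, 1, 3, effect=0.0)
        st_.exclusive_markers = [("up", cond, 4.0)]
        m = simulate_expression(design, st_, 50, seed=1)
        ranked = rank_genes(m, cond, "Mb")
        assert ranked.index[0] == "up"

    def test_identical_groups_lexicographic_ties(self):
        design = make_design(2, 4, "Mb", seed=0)
        st_ = module_recovery_structure(design, 1, 3, effect=0.0)
        st_.noise_sd = 0.0
        m = simulate_expression(design, st_, 20, seed=0)
        cond = design["condition"].unique()[1]
        ranked = rank_genes(m, cond, "Mb")
        assert np.allclose(ranked.to_numpy(), 0.0)
        assert list(ranked.index) == sorted(ranked.index)

    def test_small_group_rejected(self):
        design = make_design(2, 2, "Mb", seed=0)
        st_ = module_recovery_structure(design, 1, 3)
        m = simulate_expression(design, st_, 10, seed=0)
        with pytest.raises(ValueError, match="needs >= 3"):
            rank_genes(m, design["condition"].unique()[1], "Mb")


class TestEnrichmentScore:
    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.sampled_from([0.0, 1.0, 2.0]))
    def test_matches_brute_force(self, seed, weight):
        rng = np.random.default_rng(seed)
        n = 40
        scores = np.sort(rng.normal(size=n))[::-1]
        genes = [f"g{i:02d}" for i in range(n)]
        ranked = pd.Series(scores, index=genes)
        gene_set = list(rng.choice(genes, size=8, replace=False))
        res = enrichment_score(ranked, gene_set, weight=weight)
        assert res.es == pytest.approx(es_brute(ranked, gene_set, weight), abs=1e-12)

    def test_top_k_set_unweighted_formula(self):
        n, k = 20, 5
        ranked = pd.Series(np.linspace(2, -2, n), index=[f"g{i:02d}" for i in range(n)])
        res = enrichment_score(ranked, list(ranked.index[:k]), weight=0.0)
        # running sum peaks right after the k-th hit: 1 - 0 misses yet
        assert res.es == pytest.approx(1.0)
        assert res.leading_edge == list(ranked.index[:k])

    def test_whole_ranking_degenerate(self):
        ranked = pd.Series([1.0, 0.5], index=["a", "b"])
        with pytest.raises(ValueError, match="entire ranking"):
            enrichment_score(ranked, ["a", "b"])

    def test_empty_intersection_rejected(self):
        ranked = pd.Series([1.0, 0.5], index=["a", "b"])
        with pytest.raises(ValueError, match="empty intersection"):
            enrichment_score(ranked, ["zz"])

    def test_reversal_flips_sign_unweighted(self):
        rng = np.random.default_rng(4)
        scores = np.sort(rng.normal(size=30))[::-1]
        ranked = pd.Series(scores, index=[f"g{i:02d}" for i in range(30)])
        gene_set = [f"g{i:02d}" for i in (0, 3, 5, 11)]
        fwd = enrichment_score(ranked, gene_set, weight=0.0).es
        rev = enrichment_score(ranked[::-1], gene_set, weight=0.0).es
        assert fwd == pytest.approx(-rev, abs=1e-12)

    def test_complement_symmetry_unweighted(self):
        rng = np.random.default_rng(9)
        genes = [f"g{i:02d}" for i in range(30)]
        ranked = pd.Series(np.sort(rng.normal(size=30))[::-1], index=genes)
        gene_set = genes[2:9]
        comp = [g for g in genes if g not in gene_set]
        es_a = enrichment_score(ranked, gene_set, weight=0.0).es
        es_b = enrichment_score(ranked, comp, weight=0.0).es
        assert es_a == pytest.approx(-es_b, abs=1e-12)


@pytest.fixture(scope="module")
def small_design():
    design = make_design(2, 3, "Mb", seed=0)
    st_ = module_recovery_structure(design, 2, 10, effect=1.5)
    m = simulate_expression(design, st_, 30, seed=1)
    sets = {
        "planted": st_.modules[1].genes,
        "baseline": st_.modules[0].genes,
        "random": list(m.genes[-10:]),
    }
    return m, sets


class TestGseaPermutation:
    def test_exhaustive_enumeration_on_3v3(self, small_design):
        m, sets = small_design
        cond = [c for c in m.conditions if c != "Mb"][0]
        res = gsea_permutation(m, cond, "Mb", sets, n_perm=10_000, mode="phenotype", seed=0)
        assert res["exact"].all()
        assert (res["n_perm"] == comb(6, 3)).all()
        # independent enumeration oracle
        cols = m.samples_of(cond) + m.samples_of("Mb")
        arr = m.values[cols].to_numpy()
        genes = np.asarray(m.genes, dtype=object)
        for nm, gene_set in sets.items():
            ess = []
            for idx in combinations(range(6), 3):
                sel = np.zeros(6, bool)
                sel[list(idx)] = True
                scores = _signal2noise(arr[:, sel], arr[:, ~sel])
                order = np.lexsort((genes, -scores))
                ess.append(es_brute(pd.Series(scores[order], index=genes[order]), gene_set))
            ess = np.asarray(ess)
            obs = enrichment_score(rank_genes(m, cond, "Mb"), gene_set).es
            same = ess[ess >= 0] if obs >= 0 else ess[ess < 0]
            p_oracle = float((np.abs(same) >= abs(obs)).mean())
            row = res[res["gene_set"] == nm].iloc[0]
            assert row["p"] == pytest.approx(p_oracle, abs=1e-12)

    def test_planted_module_tops_ranking(self, demo):
        m, structure = demo
        sets = {f"module_{i + 1}": mod.genes for i, mod in enumerate(structure.modules)}
        conds = m.conditions
        res = gsea_permutation(m, conds[2], "Mb", sets, n_perm=400, mode="phenotype", seed=2)
        top = res.iloc[0]
        assert top["gene_set"] == "module_3"  # module planted for conds[2]
        assert top["p"] < 0.05
        assert top["nes"] > 1

    def test_geneset_mode_deterministic(self, small_design):
        m, sets = small_design
        cond = [c for c in m.conditions if c != "Mb"][0]
        a = gsea_permutation(m, cond, "Mb", sets, n_perm=200, mode="geneset", seed=5)
        b = gsea_permutation(m, cond, "Mb", sets, n_perm=200, mode="geneset", seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_missing_set_rejected(self, small_design):
        m, _ = small_design
        cond = [c for c in m.conditions if c != "Mb"][0]
        with pytest.raises(ValueError, match="ghost"):
            gsea_permutation(m, cond, "Mb", {"ghost": ["nope"]}, n_perm=100)


class TestVolcano:
    @pytest.mark.parametrize(
        "nes,p,enriched,depleted",
        [(1.5, 0.01, True, False), (-1.5, 0.01, False, True), (0.5, 0.001, False, False)],
    )
    def test_flag_logic(self, nes, p, enriched, depleted):
        res = pd.DataFrame({"nes": [nes], "p": [p]})
        out = volcano_table(res, nes_min=1.0, p_max=0.05)
        assert bool(out["enriched"].iloc[0]) is enriched
        assert bool(out["depleted"].iloc[0]) is depleted


class TestORA:
    def test_exact_minimal_p_matches_combinatorics(self):
        universe = [f"g{i}" for i in range(12)]
        term = universe[:4]
        out = ora_hypergeometric(set(term), universe, {"t": term})
        assert out["p"].iloc[0] == pytest.approx(1.0 / comb(12, 4), abs=1e-12)

    def test_brute_force_enumeration_small_universe(self):
        rng = np.random.default_rng(0)
        universe = [f"g{i}" for i in range(10)]
        term = universe[2:7]
        query = list(rng.choice(universe, size=4, replace=False))
        k_obs = len(set(query) & set(term))
        total = hits = 0
        for combo in combinations(universe, 4):
            total += 1
            if len(set(combo) & set(term)) >= k_obs:
                hits += 1
        out = ora_hypergeometric(set(query), universe, {"t": term})
        assert out["p"].iloc[0] == pytest.approx(hits / total, abs=1e-12)

    def test_null_queries_calibrated(self):
        rng = np.random.default_rng(1)
        universe = [f"g{i}" for i in range(100)]
        term = universe[:20]
        ps = []
        for _ in range(1000):
            query = set(rng.choice(universe, size=10, replace=False))
            ps.append(ora_hypergeometric(query, universe, {"t": term})["p"].iloc[0])
        # hypergeometric p is conservative/discrete: mean p >= 0.5-ish and
        # small-p rate at or below nominal
        assert (np.array(ps) < 0.05).mean() <= 0.07

    def test_empty_query_rejected(self):
        with pytest.raises(ValueError):
            ora_hypergeometric(set(), {"a"}, {"t": ["a"]})

    def test_query_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="outside the universe"):
            ora_hypergeometric({"zz"}, {"a"}, {"t": ["a"]})
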