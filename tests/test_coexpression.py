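"""Coexpression-module contracts: TOM against a brute-force triple loop,
eigengenes against an independent SVD, planted-module recovery, and
eigengene-trait correlation against the point-biserial closed form."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score

from macspectrum.containers import ExpressionMatrix
from macspectrum.coexpression import (
    adjacency_matrix,
    detect_modules,
    module_assignments,
    module_eigengene,
    module_trait_correlation,
    pick_soft_threshold,
    scale_free_fit,
    tf_subnetwork_correlations,
    topological_overlap,
    _build_module,
)
from macspectrum.synthetic import (
    PlantedStructure,
    make_design,
    module_recovery_structure,
    simulate_expression,
    within_module_correlation,
)


def tom_brute(a):
    """Independent triple-loop TOM oracle."""
    n = a.shape[0]
    k = a.sum(axis=1)
    out = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(n))
            out[i, j] = (shared + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return out


class TestAdjacencyAndPower:
    def test_power_one_is_plain_absolute_correlation(self, tiny_matrix):
        a = adjacency_matrix(tiny_matrix, power=1).to_numpy()
        r = np.abs(np.corrcoef(tiny_matrix.values.to_numpy()))
        np.fill_diagonal(r, 0.0)
        assert np.allclose(a, r)

    def test_selected_power_separates_planted_modules(self, module_fixture):
        m, structure = module_fixture
        power, _ = pick_soft_threshold(m, powers=[2, 4, 6, 8], target_r2=0.8)
        a = adjacency_matrix(m, power=power).to_numpy()
        idx = {g: i for i, g in enumerate(m.genes)}
        within, between = [], []
        mods = [np.array([idx[g] for g in mod.genes]) for mod in structure.modules]
        for mi_, rows in enumerate(mods):
            sub = a[np.ix_(rows, rows)]
            within.append(sub[np.triu_indices_from(sub, 1)].mean())
            for rows2 in mods[mi_ + 1 :]:
                between.append(a[np.ix_(rows, rows2)].mean())
        assert np.mean(within) >= 10 * np.mean(between)

    def test_zero_target_returns_smallest_power(self, module_fixture):
        m, _ = module_fixture
        power, _ = pick_soft_threshold(m, powers=[3, 5, 7], target_r2=0.0)
        assert power == 3

    def test_too_few_genes_rejected(self, tiny_matrix):
        with pytest.raises(ValueError):
            pick_soft_threshold(tiny_matrix)


class TestTopologicalOverlap:
    def test_two_gene_unit_adjacency(self):
        a = np.array([[0.0, 1.0], [1.0, 0.0]])
        tom = topological_overlap(a)
        assert tom[0, 1] == pytest.approx(1.0)

    def test_zero_adjacency(self):
        tom = topological_overlap(np.zeros((4, 4)))
        assert np.allclose(tom - np.eye(4), 0.0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_brute_force_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.uniform(0, 1, size=(6, 6))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0.0)
        tom = topological_overlap(a)
        assert np.allclose(tom, tom_brute(a), atol=1e-12)
        assert tom.min() >= 0.0 and tom.max() <= 1.0 + 1e-12
        assert np.allclose(tom, tom.T)

    def test_invalid_entries_rejected(self):
        bad = np.array([[0.0, 1.5], [1.5, 0.0]])
        with pytest.raises(ValueError):
            topological_overlap(bad)


class TestModuleEigengene:
    def test_identical_genes_explain_everything(self, module_fixture):
        m, _ = module_fixture
        dup = m.values.iloc[[0]].to_numpy()
        frame = pd.DataFrame(np.vstack([dup, dup, dup]), index=list("abc"), columns=m.samples)
        mm = ExpressionMatrix(frame, m.design.copy())
        eig, ve = module_eigengene(mm, ["a", "b", "c"])
        assert ve == pytest.approx(1.0)
        prof = (dup[0] - dup[0].mean()) / dup[0].std()
        assert abs(np.corrcoef(eig, prof)[0, 1]) == pytest.approx(1.0)
        assert np.corrcoef(eig, prof)[0, 1] > 0  # sign convention

    def test_anticorrelated_pair_sign_tiebreak(self, module_fixture):
        m, _ = module_fixture
        design = m.design.iloc[:3].copy()
        design["condition"] = "c"
        design["is_baseline"] = True
        frame = pd.DataFrame([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]], index=["up", "dn"],
                             columns=design.index)
        mm = ExpressionMatrix(frame, design)
        eig, ve = module_eigengene(mm, ["up", "dn"])
        assert ve == pytest.approx(1.0)
        # mean standardized profile is flat; tie broken toward the first gene
        z_first = np.array([-1, 0, 1]) / np.std([1, 2, 3])
        assert float(np.dot(eig, z_first)) > 0

    def test_matches_independent_svd(self, module_fixture):
        m, structure = module_fixture
        genes = structure.modules[2].genes
        eig, ve = module_eigengene(m, genes)
        sub = m.values.loc[genes].to_numpy()
        z = (sub - sub.mean(1, keepdims=True)) / sub.std(1, keepdims=True)
        _, s, vt = np.linalg.svd(z)
        ref = vt[0] if np.dot(vt[0], z.mean(0)) > 0 else -vt[0]
        assert np.allclose(eig.to_numpy(), ref, atol=1e-10)
        assert ve == pytest.approx(s[0] ** 2 / (s**2).sum())

    def test_rank_zero_rejected(self, module_fixture):
        m, _ = module_fixture
        frame = pd.DataFrame(np.ones((2, m.n_samples)), index=["f1", "f2"], columns=m.samples)
        mm = ExpressionMatrix(frame, m.design.copy())
        with pytest.raises(ValueError, match="rank 0"):
            module_eigengene(mm, ["f1", "f2"])


class TestDetectModules:
    def test_recovers_planted_modules(self, module_fixture):
        m, structure = module_fixture
        tom = topological_overlap(adjacency_matrix(m, power=6))
        mods = detect_modules(m, tom, min_size=30, cut_height=0.95, merge_r=0.8)
        assert len(mods) == 6
        truth_map = {g: i + 1 for i, mod in enumerate(structure.modules) for g in mod.genes}
        truth = [truth_map.get(g, 0) for g in m.genes]
        pred = module_assignments(mods, m.genes).to_numpy()
        assert adjusted_rand_score(truth, pred) >= 0.9

    def test_pure_noise_finds_no_large_modules(self):
        found = 0
        for seed in range(5):
            design = make_design(4, 8, "Mb", seed=seed)
            m = simulate_expression(design, PlantedStructure(noise_sd=0.5), 150, seed=seed)
            tom = topological_overlap(adjacency_matrix(m, power=6))
            mods = detect_modules(m, tom, min_size=30, cut_height=0.95, merge_r=0.8)
            found += sum(1 for mm in mods if len(mm) >= 30)
        assert found == 0

    def test_gene_order_invariance(self, module_fixture):
        m, _ = module_fixture
        tom = topological_overlap(adjacency_matrix(m, power=6))
        mods1 = detect_modules(m, tom, min_size=30, cut_height=0.95, merge_r=0.8)
        rng = np.random.default_rng(3)
        perm = rng.permutation(m.n_genes)
        m2 = ExpressionMatrix(m.values.iloc[perm], m.design.copy())
        tom2 = topological_overlap(adjacency_matrix(m2, power=6))
        mods2 = detect_modules(m2, tom2, min_size=30, cut_height=0.95, merge_r=0.8)
        sets1 = {frozenset(mm.genes) for mm in mods1}
        sets2 = {frozenset(mm.genes) for mm in mods2}
        assert sets1 == sets2

    def test_min_size_guard(self, module_fixture):
        m, _ = module_fixture
        tom = topological_overlap(adjacency_matrix(m, power=6))
        with pytest.raises(ValueError):
            detect_modules(m, tom, min_size=2)


class TestModuleTrait:
    def test_driver_condition_near_point_biserial(self, module_fixture):
        m, structure = module_fixture
        r, p, q = module_trait_correlation(
            [_build_module(m, i + 1, mod.genes) for i, mod in enumerate(structure.modules)],
            m.design,
        )
        for i, mod in enumerate(structure.modules):
            cond = mod.driver_conditions[0]
            ind = (m.design["condition"] == cond).to_numpy(float)
            # eigengene averages 50 genes: residual noise shrinks by sqrt(50)
            expected = np.sqrt(
                within_module_correlation(mod.effect, structure.noise_sd / np.sqrt(50), ind)
            )
            assert r.loc[i + 1].abs().idxmax() == cond
            assert abs(r.loc[i + 1, cond]) == pytest.approx(expected, abs=0.03)

    def test_constant_eigengene_flat(self, module_fixture):
        m, _ = module_fixture
        from macspectrum.containers import GeneModule

        flat = GeneModule(1, ["x"], pd.Series(np.ones(m.n_samples), index=m.samples), 1.0, None)
        r, p, q = module_trait_correlation([flat], m.design)
        assert np.allclose(r.to_numpy(), 0.0)
        assert np.allclose(p.to_numpy(), 1.0)

    def test_label_permutation_destroys_signal(self, module_fixture):
        m, structure = module_fixture
        mod = _build_module(m, 1, structure.modules[1].genes)
        r_obs = module_trait_correlation([mod], m.design)[0].abs().max(axis=1).iloc[0]
        rng = np.random.default_rng(0)
        null_max = []
        for _ in range(200):
            design = m.design.copy()
            design["condition"] = rng.permutation(design["condition"].to_numpy())
            design["is_baseline"] = design["condition"] == m.baseline
            null_max.append(module_trait_correlation([mod], design)[0].abs().max(axis=1).iloc[0])
        assert r_obs > np.quantile(null_max, 0.99)


class TestTFSubnetwork:
    def test_planted_codriven_pair_recovered(self, module_fixture):
        m, structure = module_fixture
        mods = [_build_module(m, i + 1, mod.genes) for i, mod in enumerate(structure.modules)]
        tfs = [structure.modules[1].genes[0], structure.modules[1].genes[1], structure.modules[2].genes[0]]
        edges = tf_subnetwork_correlations(m, mods, [2], tfs, r_min=0.5)
        pairs = set(map(frozenset, zip(edges["tf_a"], edges["tf_b"])))
        assert frozenset(tfs[:2]) in pairs

    def test_unknown_tf_rejected(self, module_fixture):
        m, structure = module_fixture
        mods = [_build_module(m, 1, structure.modules[0].genes)]
        with pytest.raises(KeyError, match="GHOST"):
            tf_subnetwork_correlations(m, mods, [1], ["GHOST"])

    def test_no_tfs_in_modules_warns_empty(self, module_fixture):
        m, structure = module_fixture
        mods = [_build_module(m, 1, structure.modules[0].genes)]
        with pytest.warns(UserWarning):
            out = tf_subnetwork_correlations(m, mods, [1], [structure.modules[3].genes[0]])
        assert len(out) == 0
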