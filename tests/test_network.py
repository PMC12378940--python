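"""Soft threshold, TOM, module detection, eigengenes, hub screen."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from triomics.network import (
    adjacency,
    correlation_p,
    detect_modules,
    mm_gs_screen,
    module_eigengene,
    module_trait_correlation,
    pick_soft_threshold,
    tom_similarity,
    variance_filter,
)
from triomics.simulate import MetabolomeTruth, feature_ids, generate_metabolome


def _block_data(seed=3, n_per_group=50):
    """150 features: five correlated blocks of varied size plus noise."""
    feats = feature_ids(150)
    sizes = [25, 20, 15, 15, 10]
    blocks, start = {}, 0
    for i, s in enumerate(sizes):
        blocks[f"b{i}"] = feats[start : start + s]
        start += s
    truth = MetabolomeTruth(
        diff_features=frozenset(), effect_size=0.0,
        module_blocks=blocks, block_cor=0.8,
    )
    abundance, meta = generate_metabolome(n_per_group, 150, truth, seed=seed)
    return np.log(abundance).T, blocks, meta


def _brute_force_tom(a: np.ndarray) -> np.ndarray:
    n = a.shape[0]
    k = a.sum(axis=0)
    tom = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(n))
            tom[i, j] = (shared + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return tom


class TestSoftThreshold:
    def test_block_data_reaches_scale_free_fit(self):
        X, _, _ = _block_data()
        beta, table = pick_soft_threshold(X, target_r2=0.6)
        assert beta >= 2
        assert table.loc[table["beta"] == beta, "fit_r2"].iloc[0] >= 0.6

    def test_returns_candidate_member(self):
        X, _, _ = _block_data()
        candidates = (2, 4, 6)
        beta, _ = pick_soft_threshold(X, candidates=candidates, target_r2=0.6)
        assert beta in candidates

    def test_degenerate_copies_warn(self):
        rng = np.random.default_rng(0)
        base = rng.standard_normal(30)
        X = pd.DataFrame({f"f{i}": base for i in range(25)})
        with pytest.warns(UserWarning):
            pick_soft_threshold(X, candidates=(1, 2), target_r2=0.6)


class TestTom:
    def test_three_node_formula(self):
        a = pd.DataFrame(
            [[0, 0.8, 0.5], [0.8, 0, 0.0], [0.5, 0.0, 0]],
            index=list("xyz"), columns=list("xyz"),
        )
        tom = tom_similarity(a)
        # TOM_xy = (0 + 0.8) / (min(1.3, 0.8) + 1 - 0.8) = 0.8
        assert tom.loc["x", "y"] == pytest.approx(0.8)

    def test_zero_adjacency_is_identity(self):
        a = pd.DataFrame(np.zeros((4, 4)))
        assert np.allclose(tom_similarity(a).to_numpy(), np.eye(4))

    def test_saturated_graph(self):
        a = pd.DataFrame(np.ones((5, 5)) - np.eye(5))
        assert np.allclose(tom_similarity(a).to_numpy(), 1.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(1)
        m = rng.uniform(0, 1, (12, 12))
        a = (m + m.T) / 2
        np.fill_diagonal(a, 0)
        tom = tom_similarity(pd.DataFrame(a)).to_numpy()
        assert np.allclose(tom, _brute_force_tom(a), atol=1e-12)
        assert tom.min() >= 0 and tom.max() <= 1
        assert np.allclose(tom, tom.T)

    def test_asymmetric_input_rejected(self):
        a = pd.DataFrame([[0, 0.5], [0.2, 0]])
        with pytest.raises(ValueError, match="symmetric"):
            tom_similarity(a)


class TestModules:
    def test_two_perfect_blocks_recovered(self):
        rng = np.random.default_rng(2)
        f1, f2 = rng.standard_normal((2, 60))
        cols = {}
        for i in range(15):
            cols[f"a{i}"] = f1 + 0.2 * rng.standard_normal(60)
        for i in range(15):
            cols[f"b{i}"] = f2 + 0.2 * rng.standard_normal(60)
        X = pd.DataFrame(cols)
        tom = tom_similarity(adjacency(X, beta=5))
        labels = detect_modules(X, tom, min_size=10, merge_height=0.25)
        mods = set(labels) - {"grey"}
        assert len(mods) == 2
        for prefix in ("a", "b"):
            members = labels[[c for c in X.columns if c.startswith(prefix)]]
            assert members.nunique() == 1

    def test_small_cluster_goes_grey(self):
        rng = np.random.default_rng(3)
        f1, f2 = rng.standard_normal((2, 50))
        cols = {f"a{i}": f1 + 0.2 * rng.standard_normal(50) for i in range(12)}
        cols |= {f"b{i}": f2 + 0.2 * rng.standard_normal(50) for i in range(5)}
        X = pd.DataFrame(cols)
        tom = tom_similarity(adjacency(X, beta=5))
        labels = detect_modules(X, tom, min_size=10, merge_height=0.0)
        small = labels[[c for c in X.columns if c.startswith("b")]]
        assert (small == "grey").all()

    def test_planted_partition_recovery(self):
        X, blocks, _ = _block_data()
        beta, _ = pick_soft_threshold(X, target_r2=0.6)
        tom = tom_similarity(adjacency(X, beta))
        labels = detect_modules(X, tom, min_size=10, merge_height=0.25)
        planted = pd.Series({f: k for k, fl in blocks.items() for f in fl})
        ari = adjusted_rand_score(planted, labels[planted.index])
        assert ari >= 0.9

    def test_variance_filter_keeps_fraction(self):
        X, _, _ = _block_data()
        assert variance_filter(X, 0.5).shape[1] == 75


class TestEigengene:
    def test_identical_features_yield_common_profile(self):
        rng = np.random.default_rng(4)
        profile = rng.standard_normal(40)
        X = pd.DataFrame({f"f{i}": profile for i in range(5)})
        labels = pd.Series("turquoise", index=X.columns)
        me = module_eigengene(X, labels)["turquoise"]
        standardized = (profile - profile.mean()) / profile.std(ddof=1)
        assert np.allclose(me, standardized, atol=1e-8)

    def test_unit_variance_and_sign_alignment(self):
        X, blocks, _ = _block_data()
        labels = pd.Series(
            {f: mod for mod, fl in blocks.items() for f in fl}
        ).reindex(X.columns, fill_value="grey")
        me = module_eigengene(X, labels)
        for mod in me.columns:
            assert me[mod].std(ddof=1) == pytest.approx(1.0)
            mean_profile = X[labels.index[labels == mod]].mean(axis=1)
            assert np.corrcoef(me[mod], mean_profile)[0, 1] > 0

    def test_eigengene_tracks_planted_factor(self):
        X, blocks, _ = _block_data()
        labels = pd.Series(
            {f: mod for mod, fl in blocks.items() for f in fl}
        ).reindex(X.columns, fill_value="grey")
        me = module_eigengene(X, labels)
        for mod, fl in blocks.items():
            # block mean is a proxy for the latent factor
            factor = X[fl].mean(axis=1)
            assert abs(np.corrcoef(me[mod], factor)[0, 1]) > 0.9

    def test_first_pc_explains_more_than_any_member(self):
        X, blocks, _ = _block_data()
        labels = pd.Series(
            {f: mod for mod, fl in blocks.items() for f in fl}
        ).reindex(X.columns, fill_value="grey")
        me = module_eigengene(X, labels)
        for mod, fl in blocks.items():
            block = X[fl]
            zs = (block - block.mean()) / block.std(ddof=1)
            def explained(v):
                v = (v - v.mean()) / v.std(ddof=1)
                return float((zs.corrwith(pd.Series(v, index=zs.index)) ** 2).sum())
            ev_me = explained(me[mod].to_numpy())
            for member in fl:
                assert ev_me >= explained(block[member].to_numpy()) - 1e-9


class TestHubScreen:
    def test_correlation_p_closed_form(self):
        # r = 0.7, n = 49 → t ≈ 6.72 → p < 1e-6
        p = correlation_p(np.array([0.7]), 49)[0]
        assert p < 1e-6

    def test_feature_equal_to_trait(self):
        rng = np.random.default_rng(5)
        trait = rng.integers(0, 2, 40).astype(float)
        X = pd.DataFrame({"hit": trait, "noise": rng.standard_normal(40)})
        labels = pd.Series("turquoise", index=X.columns)
        me = module_eigengene(X, labels)
        res = mm_gs_screen(X, labels, me, trait)
        assert res.gs["hit"] == pytest.approx(1.0)
        assert res.gs_p["hit"] < 1e-12

    def test_hub_screen_thresholds_and_monotonicity(self):
        feats = feature_ids(40)
        truth = MetabolomeTruth(
            diff_features=frozenset(feats[:20]), effect_size=1.5,
            module_blocks={"b": feats[:20]}, block_cor=0.8,
        )
        ab, meta = generate_metabolome(30, 40, truth, seed=6)
        X = np.log(ab).T
        trait = (meta["group"] == "DD").astype(float).to_numpy()
        labels = pd.Series("grey", index=X.columns, dtype=object)
        labels[feats[:20]] = "turquoise"
        me = module_eigengene(X, labels)
        lenient = mm_gs_screen(X, labels, me, trait, mm_min=0.5, gs_min=0.1)
        strict = mm_gs_screen(X, labels, me, trait, mm_min=0.8, gs_min=0.4)
        assert lenient.hubs.sum() > 0
        assert set(strict.hubs.index[strict.hubs]) <= set(
            lenient.hubs.index[lenient.hubs]
        )
        # grey features are never hubs
        assert not lenient.hubs[labels == "grey"].any()

    def test_mm_boundary_is_strict(self):
        # a feature with MM exactly at the threshold is not a hub
        rng = np.random.default_rng(7)
        trait = np.array([0.0, 1.0] * 20)
        base = trait + 0.3 * rng.standard_normal(40)
        X = pd.DataFrame({f"f{i}": base + 0.3 * rng.standard_normal(40) for i in range(8)})
        labels = pd.Series("turquoise", index=X.columns)
        me = module_eigengene(X, labels)
        res = mm_gs_screen(X, labels, me, trait, mm_min=1.0)  # nothing exceeds 1
        assert not res.hubs.any()

    def test_module_trait_correlation_table(self):
        X, blocks, meta = _block_data()
        labels = pd.Series(
            {f: mod for mod, fl in blocks.items() for f in fl}
        ).reindex(X.columns, fill_value="grey")
        me = module_eigengene(X, labels)
        trait = (meta["group"] == "DD").astype(float).to_numpy()
        mt = module_trait_correlation(me, trait)
        assert set(mt.index) == set(blocks)
        assert ((mt["p"] > 0) & (mt["p"] <= 1)).all()

    def test_too_few_samples_rejected(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [2.0, 1.0, 3.0]})
        labels = pd.Series("turquoise", index=X.columns)
        me = pd.DataFrame({"turquoise": [0.1, 0.2, 0.3]})
        with pytest.raises(ValueError):
            mm_gs_screen(X, labels, me, [0, 1, 0])
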