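"""Co-expression network construction, module detection and traits."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from frontloadseq.coexpression import (
    GREY,
    cut_modules,
    merge_close_modules,
    module_eigengenes,
    module_sizes,
    module_trait_correlation,
    signed_adjacency,
    tom_similarity,
)
from tests.conftest import planted_blocks


def _expr(rows, prefix="g"):
    rows = np.atleast_2d(rows)
    return pd.DataFrame(
        rows, index=[f"{prefix}{i}" for i in range(len(rows))]
    )


class TestSignedAdjacency:
    def test_perfect_correlation_and_anticorrelation(self):
        x = np.arange(10.0)
        expr = _expr([x, 2 * x + 1, -x])
        a = signed_adjacency(expr, beta=5).to_numpy()
        assert a[0, 1] == pytest.approx(1.0)
        assert a[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_zero_correlation_maps_to_half_to_the_beta(self):
        x = np.array([1.0, 1.0, -1.0, -1.0])
        y = np.array([1.0, -1.0, 1.0, -1.0])  # exactly orthogonal
        a = signed_adjacency(_expr([x, y]), beta=5).to_numpy()
        assert a[0, 1] == pytest.approx(0.5**5)

    def test_zero_variance_gene_named_in_error(self):
        expr = _expr([np.arange(5.0), np.ones(5)])
        with pytest.raises(ValueError, match="g1"):
            signed_adjacency(expr)


class TestTom:
    def test_three_node_hand_case(self):
        a = np.full((3, 3), 0.5)
        np.fill_diagonal(a, 1.0)
        tom = tom_similarity(pd.DataFrame(a)).to_numpy()
        assert tom[0, 1] == pytest.approx((0.25 + 0.5) / (1 + 1 - 0.5))

    def test_isolated_nodes_have_zero_overlap(self):
        a = np.eye(4)
        a[2, 3] = a[3, 2] = 0.9
        tom = tom_similarity(pd.DataFrame(a)).to_numpy()
        assert tom[0, 1] == 0.0

    def test_matches_brute_force_triple_sum(self):
        rng = np.random.default_rng(0)
        worst = 0.0
        for _ in range(25):
            n = 10
            a = rng.uniform(size=(n, n))
            a = (a + a.T) / 2
            np.fill_diagonal(a, 1.0)
            tom = tom_similarity(pd.DataFrame(a)).to_numpy()
            for i in range(n):
                for j in range(n):
                    if i == j:
                        continue
                    s = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
                    ki = sum(a[i, u] for u in range(n) if u != i)
                    kj = sum(a[j, u] for u in range(n) if u != j)
                    ref = (s + a[i, j]) / (min(ki, kj) + 1 - a[i, j])
                    worst = max(worst, abs(tom[i, j] - ref))
        assert worst < 1e-12

    def test_bounds_symmetry_diagonal(self):
        rng = np.random.default_rng(1)
        a = rng.uniform(size=(20, 20))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        tom = tom_similarity(pd.DataFrame(a)).to_numpy()
        assert np.all((tom >= 0) & (tom <= 1))
        assert np.allclose(tom, tom.T)
        assert np.allclose(np.diag(tom), 1.0)

    def test_asymmetric_input_rejected(self):
        a = np.eye(3)
        a[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            tom_similarity(pd.DataFrame(a))


class TestCutModules:
    def test_planted_blocks_recovered(self):
        expr, truth = planted_blocks(seed=0)
        tom = tom_similarity(signed_adjacency(expr, 5))
        labels = cut_modules(1.0 - tom, min_module_size=30, deep_split=1)
        ari = adjusted_rand_score(truth, pd.factorize(labels)[0])
        assert ari >= 0.9
        noise_labels = labels[truth == -1]
        assert (noise_labels == GREY).mean() > 0.8

    def test_homogeneous_noise_yields_no_modules(self):
        hits = 0
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            expr = _expr(rng.normal(size=(150, 46)))
            tom = tom_similarity(signed_adjacency(expr, 5))
            labels = cut_modules(1.0 - tom)
            hits += int((labels != GREY).any())
        assert hits == 0

    def test_block_below_minimum_size_not_detected(self):
        rng = np.random.default_rng(2)
        f = rng.normal(size=46)
        rows = [2 * f + rng.normal(size=46) for _ in range(25)]
        rows += [rng.normal(size=46) for _ in range(75)]
        tom = tom_similarity(signed_adjacency(_expr(rows), 5))
        labels = cut_modules(1.0 - tom, min_module_size=30)
        assert (labels == GREY).all()

    def test_fewer_genes_than_min_size_all_grey_with_warning(self):
        rng = np.random.default_rng(3)
        expr = _expr(rng.normal(size=(10, 20)))
        tom = tom_similarity(signed_adjacency(expr, 5))
        with pytest.warns(UserWarning):
            labels = cut_modules(1.0 - tom, min_module_size=30)
        assert (labels == GREY).all()


class TestEigengenes:
    def test_identical_profiles_reproduce_the_profile(self):
        rng = np.random.default_rng(4)
        profile = rng.normal(size=30)
        z = (profile - profile.mean()) / profile.std()
        expr = _expr([profile.copy() for _ in range(10)])
        labels = pd.Series("blue", index=expr.index)
        eig = module_eigengenes(expr, labels).loc["blue"].to_numpy()
        np.testing.assert_allclose(eig, z, atol=1e-10)

    def test_sign_orientation_invariant_to_member_flips(self):
        rng = np.random.default_rng(5)
        f = rng.normal(size=40)
        expr = _expr([2 * f + rng.normal(size=40) for _ in range(20)])
        labels = pd.Series("blue", index=expr.index)
        eig1 = module_eigengenes(expr, labels).loc["blue"]
        eig2 = module_eigengenes(-expr, labels).loc["blue"]
        r = np.corrcoef(eig1, eig2)[0, 1]
        assert abs(abs(r) - 1.0) < 1e-10
        # orientation: positive mean correlation with members in both cases
        mean_cor1 = np.mean([np.corrcoef(eig1, row)[0, 1] for _, row in expr.iterrows()])
        mean_cor2 = np.mean([np.corrcoef(eig2, row)[0, 1] for _, row in (-expr).iterrows()])
        assert mean_cor1 > 0 and mean_cor2 > 0

    def test_single_factor_module_tracks_latent_factor(self):
        rng = np.random.default_rng(6)
        f = rng.normal(size=46)
        expr = _expr([2 * f + rng.normal(size=46) for _ in range(50)])
        labels = pd.Series("blue", index=expr.index)
        eig = module_eigengenes(expr, labels).loc["blue"]
        assert abs(np.corrcoef(eig, f)[0, 1]) >= 0.95

    def test_singleton_module_warns_and_standardizes(self):
        rng = np.random.default_rng(7)
        expr = _expr(rng.normal(size=(1, 20)))
        labels = pd.Series("blue", index=expr.index)
        with pytest.warns(UserWarning, match="single"):
            eig = module_eigengenes(expr, labels).loc["blue"]
        assert eig.std(ddof=0) == pytest.approx(1.0)


class TestMergeCloseModules:
    @staticmethod
    def _two_module_expr(shared_factor: bool, seed=8):
        rng = np.random.default_rng(seed)
        f1 = rng.normal(size=46)
        f2 = f1 if shared_factor else rng.normal(size=46)
        rows = [3 * f1 + rng.normal(size=46) for _ in range(35)]
        rows += [3 * f2 + rng.normal(size=46) for _ in range(35)]
        expr = _expr(rows)
        labels = pd.Series(["blue"] * 35 + ["brown"] * 35, index=expr.index)
        return expr, labels

    def test_same_factor_modules_merge(self):
        expr, labels = self._two_module_expr(shared_factor=True)
        merged = merge_close_modules(expr, labels, cut_height=0.15)
        assert len(set(merged) - {GREY}) == 1

    def test_orthogonal_modules_unchanged(self):
        expr, labels = self._two_module_expr(shared_factor=False)
        merged = merge_close_modules(expr, labels, cut_height=0.15)
        assert len(set(merged) - {GREY}) == 2

    def test_zero_cut_height_never_merges(self):
        expr, labels = self._two_module_expr(shared_factor=True)
        merged = merge_close_modules(expr, labels, cut_height=0.0)
        assert len(set(merged) - {GREY}) == 2

    def test_merging_never_increases_count_and_respects_threshold(self):
        expr, truth = planted_blocks(seed=9, n_blocks=4, block_size=40, n_noise=30)
        tom = tom_similarity(signed_adjacency(expr, 5))
        labels = cut_modules(1.0 - tom)
        merged = merge_close_modules(expr, labels, cut_height=0.15)
        assert len(set(merged) - {GREY}) <= len(set(labels) - {GREY})
        eig = module_eigengenes(expr, merged)
        if len(eig) >= 2:
            cor = np.corrcoef(eig.to_numpy())
            off = cor[np.triu_indices(len(eig), k=1)]
            assert np.all(off <= 0.87)


class TestModuleTrait:
    def test_trait_equal_to_eigengene_has_unit_correlation(self):
        rng = np.random.default_rng(10)
        f = rng.normal(size=46)
        expr = _expr([2 * f + rng.normal(size=46) for _ in range(30)])
        labels = pd.Series("blue", index=expr.index)
        eig = module_eigengenes(expr, labels)
        traits = pd.DataFrame({"t": eig.loc["blue"].to_numpy()}, index=eig.columns)
        r, p = module_trait_correlation(eig, traits)
        assert r.loc["blue", "t"] == pytest.approx(1.0)
        assert p.loc["blue", "t"] < 1e-12

    def test_p_value_matches_t_distribution_closed_form(self):
        """Sample r = 0.5 at n = 46 gives t ~ 3.83, two-sided p ~ 4e-4."""
        n, r_target = 46, 0.5
        rng = np.random.default_rng(11)
        x = rng.normal(size=n)
        z = rng.normal(size=n)
        x = (x - x.mean()) / x.std()
        z = z - z.mean()
        z -= x * (x @ z) / (x @ x)  # orthogonalize
        z /= z.std()
        y = r_target * x + np.sqrt(1 - r_target**2) * z
        eig = pd.DataFrame([x], index=["blue"], columns=range(n))
        traits = pd.DataFrame({"t": y}, index=range(n))
        r, p = module_trait_correlation(eig, traits)
        assert r.loc["blue", "t"] == pytest.approx(0.5, abs=1e-10)
        t = 0.5 * np.sqrt(44) / np.sqrt(0.75)
        assert p.loc["blue", "t"] == pytest.approx(2 * stats.t.sf(t, 44), rel=1e-6)

    def test_consistent_sample_permutation_leaves_matrix_unchanged(self):
        rng = np.random.default_rng(12)
        eig = pd.DataFrame(rng.normal(size=(3, 20)),
                           index=["blue", "brown", "turquoise"])
        traits = pd.DataFrame(rng.normal(size=(20, 2)), columns=["a", "b"])
        r1, _ = module_trait_correlation(eig, traits)
        perm = rng.permutation(20)
        r2, _ = module_trait_correlation(eig.iloc[:, perm], traits.iloc[perm])
        pd.testing.assert_frame_equal(r1, r2)

    def test_short_trait_yields_missing_cell_with_warning(self):
        rng = np.random.default_rng(13)
        eig = pd.DataFrame(rng.normal(size=(3, 10)), index=["b", "c", "d"])
        traits = pd.DataFrame({"t": [1.0, 2.0] + [np.nan] * 8}, index=eig.columns)
        with pytest.warns(UserWarning, match="fewer than 3"):
            r, p = module_trait_correlation(eig, traits)
        assert r["t"].isna().all()


def test_module_sizes_sorted_descending():
    labels = pd.Series(["blue"] * 5 + ["brown"] * 3 + [GREY] * 2)
    sizes = module_sizes(labels)
    assert list(sizes.index) == ["blue", "brown"]
    assert list(sizes) == [5, 3]
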