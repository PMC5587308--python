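"""IndVal, permutation p-values, weighted silhouettes, typology selection."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import silhouette_score

import assemblage as asm
from assemblage.indicators import DIAGNOSTIC_INDICES
from conftest import brute_force_indval


class TestIndVal:
    def test_perfect_indicator_scores_one(self):
        X = np.array([[80, 20], [70, 30], [0, 100], [0, 100]], dtype=float)
        res = asm.indval(X, [1, 1, 2, 2])
        assert res.loc["0", "indval"] == pytest.approx(1.0)
        assert res.loc["0", "cluster"] == 1

    def test_uninformative_species_scores_one_over_k(self):
        X = np.full((9, 1), 10.0)
        res = asm.indval(X, [1, 1, 1, 2, 2, 2, 3, 3, 3])
        assert res["indval"].iloc[0] == pytest.approx(1 / 3)

    def test_hand_computed_two_cluster_example(self):
        # IVs (10, 10 | 0, 30): A1 = 0.4, B1 = 1; A2 = 0.6, B2 = 0.5 -> 0.4
        X = np.array([[10.0], [10.0], [0.0], [30.0]])
        res = asm.indval(X, [1, 1, 2, 2])
        assert res["indval"].iloc[0] == pytest.approx(0.4)
        assert res["cluster"].iloc[0] == 1

    def test_specificity_sums_to_one(self, planted, planted_model):
        _, _, _, iv = planted
        memb = planted_model.cut(4)
        X, labels = iv.to_numpy(), memb.to_numpy()
        brute, _ = brute_force_indval(X, labels)
        res = asm.indval(iv, memb)
        assert np.allclose(res["indval"].to_numpy(), brute, atol=1e-12)
        # A over clusters sums to 1 for species with any IV mass
        for s in range(X.shape[1]):
            tot = sum(X[labels == c, s].mean() for c in np.unique(labels))
            if tot > 0:
                A = [X[labels == c, s].mean() / tot for c in np.unique(labels)]
                assert sum(A) == pytest.approx(1.0)

    def test_membership_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            asm.indval(np.ones((3, 1)), [1, 1])


class TestPermutationPValues:
    def test_perfect_indicator_attains_minimal_p(self):
        rng = np.random.default_rng(0)
        X = np.zeros((20, 2))
        X[:10, 0] = rng.uniform(50, 100, 10)
        X[10:, 1] = rng.uniform(50, 100, 10)
        res = asm.indval_pvalues(X, [1] * 10 + [2] * 10, n_perm=999, rng_seed=1)
        assert res["p_value"].iloc[0] == pytest.approx(1 / 1000)

    def test_constant_species_p_is_one(self):
        X = np.column_stack([np.full(8, 25.0), np.arange(1.0, 9.0)])
        res = asm.indval_pvalues(X, [1, 1, 1, 1, 2, 2, 2, 2], n_perm=199, rng_seed=0)
        assert res["p_value"].iloc[0] == pytest.approx(1.0)

    def test_agrees_with_exhaustive_enumeration(self):
        from sympy.utilities.iterables import multiset_permutations

        X = np.array(
            [[60, 40, 0], [70, 30, 0], [50, 50, 0], [10, 0, 90], [0, 20, 80], [5, 5, 90]],
            dtype=float,
        )
        memb = np.array([1, 1, 1, 2, 2, 2])
        obs, _ = brute_force_indval(X, memb)
        count, total = np.zeros(X.shape[1]), 0
        for labs in multiset_permutations(memb.tolist()):
            stat, _ = brute_force_indval(X, np.array(labs))
            count += stat >= obs - 1e-12
            total += 1
        exact = count / total
        n_perm = 999
        res = asm.indval_pvalues(X, memb, n_perm=n_perm, rng_seed=5)
        tol = 3 * np.sqrt(exact * (1 - exact) / n_perm) + 1 / (n_perm + 1)
        assert (np.abs(res["p_value"].to_numpy() - exact) <= tol).all()


class TestSilhouette:
    def test_perfect_separation(self):
        D = np.array([[0, 0, 1, 1], [0, 0, 1, 1], [1, 1, 0, 0], [1, 1, 0, 0]], dtype=float)
        s = asm.silhouette_mean(D, np.ones(4), [1, 1, 2, 2])
        assert s == pytest.approx(1.0)

    def test_equidistant_seed_scores_zero(self):
        # seed 0: a = d(0,1) = 0.4 = b = d(0,2) -> s0 = 0
        # seed 1: a = 0.4, b = 0.8 -> s1 = 0.5; seed 2: singleton -> s2 = 0
        D = squareform([0.4, 0.4, 0.8])
        s_all = asm.silhouette_mean(D, np.ones(3), [1, 1, 2])
        assert s_all == pytest.approx(0.5 / 3)

    def test_unit_sizes_match_sklearn(self):
        rng = np.random.default_rng(2)
        X = rng.dirichlet(np.ones(5), size=40) * 100
        labels = rng.integers(0, 3, size=40)
        D = squareform(pdist(X, metric="braycurtis"))
        ours = asm.silhouette_mean(D, np.ones(40), labels)
        ref = silhouette_score(D, labels, metric="precomputed")
        assert ours == pytest.approx(ref, abs=1e-12)

    def test_duplicate_expansion_equals_plot_level(self):
        """Seeds of coincident plots give the same mean silhouette as plot level."""
        rng = np.random.default_rng(3)
        base = rng.dirichlet(np.ones(4), size=10) * 100
        reps = rng.integers(1, 5, size=10)
        labels_seed = rng.integers(0, 2, size=10)
        X = np.repeat(base, reps, axis=0)
        labels_plot = np.repeat(labels_seed, reps)
        D_seed = squareform(pdist(base, metric="braycurtis"))
        D_plot = squareform(pdist(X, metric="braycurtis"))
        ours = asm.silhouette_mean(D_seed, reps, labels_seed)
        plot_level = asm.silhouette_mean(D_plot, np.ones(len(X)), labels_plot)
        assert ours == pytest.approx(plot_level, abs=1e-12)

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            asm.silhouette_mean(np.zeros((3, 3)), np.ones(3), [1, 1, 1])


@pytest.fixture(scope="module")
def scan(planted, planted_model):
    _, _, _, iv = planted
    cfg = asm.SelectionConfig(alpha=0.05, n_perm=199, k_range=(2, 8), rng_seed=5)
    return asm.scan_hierarchy(iv, planted_model.dendrogram_, planted_model.seed_set_, cfg)


class TestScanAndSelect:
    def test_single_level_range_one_row(self, planted, planted_model):
        _, _, _, iv = planted
        cfg = asm.SelectionConfig(n_perm=99, k_range=(2, 2), rng_seed=0)
        diag = asm.scan_hierarchy(iv, planted_model.dendrogram_, planted_model.seed_set_, cfg)
        assert len(diag) == 1 and diag.index[0] == 2

    def test_all_clusters_covered_at_true_k(self, scan):
        assert bool(scan.loc[4, "all_clusters_covered"])

    def test_rerun_identical(self, planted, planted_model, scan):
        _, _, _, iv = planted
        cfg = asm.SelectionConfig(alpha=0.05, n_perm=199, k_range=(2, 8), rng_seed=5)
        again = asm.scan_hierarchy(iv, planted_model.dendrogram_, planted_model.seed_set_, cfg)
        pd.testing.assert_frame_equal(scan, again)

    def test_true_k_among_top_candidates(self, scan):
        opt = asm.select_optima(scan)
        assert 4 in opt.index[:2]

    def test_monotone_index_global_best_at_extreme(self):
        diag = pd.DataFrame(
            {
                "sum_sig_indval": [1.0, 2.0, 3.0],
                "n_sig_species": [5, 5, 5],
                "mean_sig_p": [0.02, 0.02, 0.02],
                "mean_silhouette": [0.1, 0.1, 0.1],
                "all_clusters_covered": [True, True, True],
            },
            index=pd.Index([2, 3, 4], name="k"),
        )
        opt = asm.select_optima(diag)
        assert bool(opt.loc[4, "global_best_sum_sig_indval"])
        assert not bool(opt.loc[3, "global_best_sum_sig_indval"])

    def test_dominating_row_flagged_in_all_indices(self):
        diag = pd.DataFrame(
            {
                "sum_sig_indval": [1.0, 5.0, 2.0],
                "n_sig_species": [3, 9, 4],
                "mean_sig_p": [0.04, 0.001, 0.03],
                "mean_silhouette": [0.1, 0.5, 0.2],
                "all_clusters_covered": [True, True, True],
            },
            index=pd.Index([2, 3, 4], name="k"),
        )
        opt = asm.select_optima(diag)
        for idx in DIAGNOSTIC_INDICES:
            assert bool(opt.loc[3, f"local_opt_{idx}"])
        assert opt.loc[3, "n_flagged_indices"] == 4

    def test_empty_eligible_set_warns(self):
        diag = pd.DataFrame(
            {
                "sum_sig_indval": [1.0],
                "n_sig_species": [1],
                "mean_sig_p": [0.5],
                "mean_silhouette": [0.0],
                "all_clusters_covered": [False],
            },
            index=pd.Index([2], name="k"),
        )
        with pytest.warns(UserWarning):
            opt = asm.select_optima(diag)
        assert opt.empty


class TestEstimator:
    def test_fit_exposes_statistics(self, planted, planted_model):
        _, _, _, iv = planted
        memb = planted_model.cut(4)
        est = asm.IndicatorSpeciesAnalysis(n_perm=99, random_state=0).fit(iv, memb)
        assert est.indval_.shape == (iv.shape[1],)
        assert ((est.p_values_ > 0) & (est.p_values_ <= 1)).all()
        assert (est.p_values_ >= 1 / 100).all()
        sig = est.significant_species()
        assert (sig["p_value"] <= 0.05).all()

    def test_planted_indicators_top_their_clusters(self, planted, planted_model):
        cfg, _, labels, iv = planted
        templates = asm.make_templates(cfg)
        memb = planted_model.cut(4)
        res = asm.indval(iv, memb)
        top = res.sort_values("indval", ascending=False).groupby("cluster").head(1)
        planted_indicators = {s for t in templates for s in t.indicator_species}
        assert set(top.index) <= planted_indicators
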