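import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from neuralplate.preprocess import knn_graph, normalize_log
from neuralplate.simulate import simulate_null_matrix
from neuralplate.spatial import (
    GraphDiffusionImputer,
    SpatialAutocorrelation,
    TrendSet,
    _autocorr_weights,
    cluster_trends,
    fit_trends,
    impute,
    knee_point,
    local_autocorrelation,
    module_cell_scores,
    module_hierarchy,
    select_spatial_genes,
)

from conftest import make_adata


def expression_adata(X):
    ds = make_adata(np.maximum(np.round(X), 0).astype(int))
    ds.layers["normalized"] = np.asarray(X, dtype=float)
    return ds


class TestKneePoint:
    def test_right_angle_corner(self):
        assert knee_point([10, 10, 10, 1, 1, 1]) == 2  # first maximal distance

    def test_straight_line_returns_zero_with_warning(self, caplog):
        with caplog.at_level("WARNING", logger="neuralplate.spatial"):
            assert knee_point(np.linspace(5, 1, 10)) == 0
        assert any("straight line" in r.message for r in caplog.records)

    def test_interior_spike(self):
        y = np.zeros(9)
        y[4] = 5.0
        # oracle: exhaustive perpendicular-distance scan to the chord (flat ⇒
        # distance equals |y|)
        assert knee_point(y) == 4

    def test_too_short(self):
        with pytest.raises(ValueError):
            knee_point([1, 2])


class TestLocalAutocorrelation:
    def test_constant_gene_convention(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(100, 3))
        X[:, 1] = 2.5
        ds = expression_adata(X)
        res = local_autocorrelation(ds, rng.normal(size=(100, 2)), k=10)
        assert res.loc["g1", "Z"] == 0.0 and res.loc["g1", "p"] == 1.0

    def test_smooth_gene_has_large_z(self):
        rng = np.random.default_rng(1)
        latent = np.sort(rng.uniform(0, 1, 300))
        X = rng.normal(size=(300, 5))
        X[:, 0] = np.sin(2 * np.pi * latent)  # smooth in the latent coordinate
        ds = expression_adata(X)
        res = local_autocorrelation(ds, latent, k=30)
        assert res.loc["g0", "Z"] >= 10

    def test_analytic_z_matches_permutation_oracle(self):
        # moderate-signal genes on 300 cells: analytic Z within 10% of the
        # z-score over 10,000 expression permutations
        rng = np.random.default_rng(2)
        n = 300
        latent = rng.uniform(0, 1, n)
        signal = np.cos(np.pi * latent)
        X = np.empty((n, 4))
        for j, a in enumerate([0.12, 0.18, 0.25, 0.35]):
            X[:, j] = a * signal + rng.normal(size=n)
        ds = expression_adata(X)
        res = local_autocorrelation(ds, latent, k=30)

        W = _autocorr_weights(latent[:, None], k=30).toarray()
        var_perm = []
        n_perm = 10_000
        for j in range(4):
            x = X[:, j]
            x = (x - x.mean()) / x.std()
            perms = np.array([rng.permutation(n) for _ in range(n_perm)])
            Xp = x[perms]  # n_perm × n
            H = np.einsum("pi,pi->p", Xp @ W, Xp)
            h_obs = x @ W @ x
            z_perm = (h_obs - H.mean()) / H.std()
            z_ana = res["Z"].iloc[j]
            if abs(z_ana) <= 6:
                assert abs(z_ana - z_perm) <= 0.1 * max(abs(z_perm), 1.0)

    def test_null_z_distribution_standard_normal(self):
        ds = simulate_null_matrix(400, 600, seed=3)
        normalize_log(ds)
        # latent independent of the tested expression (geometry from an
        # independent realization of the same null process)
        rng = np.random.default_rng(4)
        latent = rng.normal(size=(400, 5))
        res = local_autocorrelation(ds, latent, k=30)
        z = res["Z"].to_numpy()
        assert abs(z.mean()) < 0.1
        assert 0.85 <= z.std() <= 1.15
        assert stats.kstest(z, "norm").pvalue > 0.01


class TestSelectSpatialGenes:
    def _frame(self, z, rng_ln, fdr=None):
        z = np.asarray(z, float)
        p = stats.norm.sf(z)
        from statsmodels.stats.multitest import multipletests

        fdr = multipletests(p, method="fdr_bh")[1] if fdr is None else fdr
        return pd.DataFrame(
            {"Z": z, "p": p, "fdr": fdr, "range": rng_ln, "H": z},
            index=[f"g{i}" for i in range(len(z))],
        )

    def test_low_range_excluded_despite_huge_z(self):
        res = self._frame([50.0, 30.0, 0.1], [0.5, 2.0, 2.0])
        sel = select_spatial_genes(res)
        assert sel == ["g1"]

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(5)
        res = self._frame(rng.uniform(0, 30, 50), rng.uniform(0, 3, 50))
        tight = set(select_spatial_genes(res, fdr_max=1e-6, z_min=15, range_min=1.5))
        loose = set(select_spatial_genes(res, fdr_max=1e-4, z_min=5, range_min=0.5))
        assert tight <= loose

    def test_knee_mode_threshold(self):
        z = np.concatenate([np.linspace(40, 20, 10), np.linspace(1, 0, 90)])
        res = self._frame(z, np.full(100, 2.0))
        sel = select_spatial_genes(res, z_min="knee")
        assert 5 <= len(sel) <= 15  # the knee separates the plateau

    def test_estimator_surface(self):
        rng = np.random.default_rng(6)
        latent = np.sort(rng.uniform(0, 1, 200))
        X = rng.normal(size=(200, 6))
        X[:, 0] = 4 * np.sin(2 * np.pi * latent) + 0.2 * rng.normal(size=200)
        sel = SpatialAutocorrelation(k=20, range_min=0.5).fit(X, latent=latent)
        assert sel.get_support()[0]
        assert sel.get_support()[1:].sum() == 0


class TestImpute:
    def test_t_zero_is_identity(self):
        rng = np.random.default_rng(7)
        ds = expression_adata(rng.normal(size=(60, 8)) + 3)
        impute(ds, rng.normal(size=(60, 2)), k=5, t=0)
        np.testing.assert_allclose(
            ds.layers["imputed"], np.asarray(ds.layers["normalized"]), atol=1e-12
        )

    def test_constant_gene_is_fixed_point(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(60, 4)) + 5
        X[:, 2] = 1.23
        ds = expression_adata(X)
        impute(ds, rng.normal(size=(60, 2)), k=5, t=3)
        np.testing.assert_allclose(ds.layers["imputed"][:, 2], 1.23, atol=1e-10)

    def test_smoothing_contracts_variance(self):
        rng = np.random.default_rng(9)
        ds = expression_adata(rng.normal(size=(100, 10)))
        impute(ds, rng.normal(size=(100, 3)), k=5, t=3)
        v_imp = ds.layers["imputed"].var(axis=0)
        v_norm = np.asarray(ds.layers["normalized"]).var(axis=0)
        assert (v_imp <= v_norm + 1e-12).all()


class TestFitTrends:
    def _adata_on_axis(self, f, n=300, noise=0.0, seed=10):
        rng = np.random.default_rng(seed)
        axis = np.sort(rng.uniform(0, 1, n))
        X = np.column_stack([f(axis) + noise * rng.normal(size=n)])
        ds = expression_adata(X)
        ds.layers["imputed"] = X.astype(float)
        return ds, axis

    def test_noiseless_linear_gene_recovered(self):
        ds, axis = self._adata_on_axis(lambda x: 2.0 * x + 1.0)
        ts = fit_trends(ds, axis, ["g0"])
        truth = 2.0 * ts.axis_grid + 1.0
        rmse = np.sqrt(np.mean((ts.trends.to_numpy()[0] - truth) ** 2))
        assert rmse <= 1e-3

    def test_constant_gene_constant_trend(self):
        ds, axis = self._adata_on_axis(lambda x: np.full_like(x, 3.3))
        ts = fit_trends(ds, axis, ["g0"])
        np.testing.assert_allclose(ts.trends.to_numpy(), 3.3, atol=1e-8)

    def test_logistic_front_inflection_position(self):
        ds, axis = self._adata_on_axis(
            lambda x: 1 / (1 + np.exp(-(x - 0.5) / 0.05)), noise=0.05
        )
        ts = fit_trends(ds, axis, ["g0"])
        y = ts.trends.to_numpy()[0]
        inflection = ts.axis_grid[np.argmax(np.gradient(y))]
        assert abs(inflection - 0.5) <= 0.05

    def test_axis_reversal_reverses_trends(self):
        rng = np.random.default_rng(11)
        axis = np.sort(rng.uniform(0, 1, 200))
        X = np.column_stack([np.sin(3 * axis) + 0.1 * rng.normal(size=200)])
        ds = expression_adata(X)
        ds.layers["imputed"] = X.astype(float)
        fwd = fit_trends(ds, axis, ["g0"]).trends.to_numpy()[0]
        rev = fit_trends(ds, -axis, ["g0"]).trends.to_numpy()[0]
        np.testing.assert_allclose(rev, fwd[::-1], atol=1e-6)

    def test_too_few_cells(self):
        ds, axis = self._adata_on_axis(lambda x: x, n=30)
        with pytest.raises(ValueError, match="at least 50"):
            fit_trends(ds, axis, ["g0"])


class TestClusterTrends:
    def _template_trends(self, n_templates=5, per=12, noise=0.1, seed=12):
        rng = np.random.default_rng(seed)
        grid = np.linspace(0, 1, 500)
        templates = [
            np.exp(-0.5 * ((grid - c) / 0.12) ** 2)
            for c in np.linspace(0.1, 0.9, n_templates)
        ]
        rows, truth = [], []
        for k_, t in enumerate(templates):
            for _ in range(per):
                rows.append(t + noise * rng.normal(size=500))
                truth.append(k_)
        trends = pd.DataFrame(rows, index=[f"g{i}" for i in range(len(rows))])
        return TrendSet(trends, grid), np.array(truth)

    def test_recovers_planted_templates(self):
        # kNN communities must be larger than k: 12-gene templates need k<12,
        # the published k=20 default matches catalogues with ≥30 genes/cluster
        ts, truth = self._template_trends(per=12)
        labels = cluster_trends(ts, k=10, seed=0)
        assert adjusted_rand_score(truth, labels) >= 0.8

    def test_recovers_templates_at_default_k(self):
        ts, truth = self._template_trends(per=30)
        labels = cluster_trends(ts, k=20, seed=0)
        assert adjusted_rand_score(truth, labels) >= 0.8

    def test_label_order_follows_peak_position(self):
        ts, truth = self._template_trends(noise=0.02)
        labels = cluster_trends(ts, k=20, seed=0)
        peaks = ts.trends.to_numpy().argmax(axis=1)
        means = [peaks[labels.to_numpy() == c].mean() for c in sorted(labels.unique())]
        assert means == sorted(means)

    def test_identical_trends_single_cluster(self):
        grid = np.linspace(0, 1, 500)
        trends = pd.DataFrame(
            np.tile(np.sin(grid), (25, 1)), index=[f"g{i}" for i in range(25)]
        )
        labels = cluster_trends(TrendSet(trends, grid), k=20, seed=0)
        assert labels.nunique() == 1

    def test_too_few_genes(self):
        grid = np.linspace(0, 1, 500)
        ts = TrendSet(pd.DataFrame(np.ones((5, 500))), grid)
        with pytest.raises(ValueError, match="smaller k"):
            cluster_trends(ts, k=20)


class TestModuleHierarchy:
    def _module_dataset(self, n=300, per=20, r=0.8, seed=13):
        rng = np.random.default_rng(seed)
        factors = rng.normal(size=(n, 3))
        cols, truth = [], []
        w = np.sqrt(r)
        for m in range(3):
            for _ in range(per):
                cols.append(w * factors[:, m] + np.sqrt(1 - r) * rng.normal(size=n))
                truth.append(m)
        X = np.column_stack(cols)
        ds = expression_adata(X + 5)
        return ds, np.array(truth)

    def test_planted_modules_pure_at_knee_cut(self):
        ds, truth = self._module_dataset()
        h = module_hierarchy(ds, list(ds.var_names))
        assert h.default_n_clusters == 3
        assert adjusted_rand_score(truth, h.default_labels) == 1.0
        assert h.median_intra_corr[h.default_n_clusters] >= 0.4

    def test_cuts_nest_and_heights_monotone(self):
        ds, _ = self._module_dataset(seed=14)
        h = module_hierarchy(ds, list(ds.var_names), cut_distances=(10.0, 6.0, 4.0))
        assert (np.diff(h.linkage[:, 2]) >= -1e-9).all()
        fine = h.labels_at_distance[4.0]
        coarse = h.labels_at_distance[10.0]
        # nesting: each fine cluster maps into exactly one coarse cluster
        for c in fine.unique():
            assert coarse[fine == c].nunique() == 1

    def test_constant_gene_dropped_with_warning(self, caplog):
        ds, _ = self._module_dataset(seed=15)
        X = np.asarray(ds.layers["normalized"])
        X[:, 0] = 7.0
        ds.layers["normalized"] = X
        with caplog.at_level("WARNING"):
            h = module_hierarchy(ds, list(ds.var_names))
        assert "g0" not in h.genes

    def test_module_scores_highest_in_home_module_cells(self):
        ds, truth = self._module_dataset(seed=16)
        h = module_hierarchy(ds, list(ds.var_names))
        scores = module_cell_scores(ds, h.default_labels)
        # cells dominated by factor 0 score highest on the module of factor 0
        f0 = np.asarray(ds.layers["normalized"])[:, truth == 0].mean(axis=1)
        top_cells = f0 > np.quantile(f0, 0.9)
        mod_of_0 = h.default_labels[f"g0"]
        col = f"module_{mod_of_0}"
        others = [c for c in scores.columns if c != col]
        assert (
            scores.loc[top_cells, col].mean()
            > scores.loc[top_cells, others].mean(axis=1).mean()
        )
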