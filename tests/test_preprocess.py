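import numpy as np
import pytest
import scipy.sparse as sp

from neuralplate.io import GeneSet
from neuralplate.preprocess import (
    exact_knn,
    knn_graph,
    normalize_log,
    pca_to_variance,
    regress_cell_cycle,
    select_hvg,
)

from conftest import make_adata


class TestNormalizeLog:
    def test_median_scaling_formula(self):
        # cell libsizes 4, 8, 12 → median 8; first cell scaled ×2 then ln1p
        ds = make_adata([[1, 1, 2], [4, 2, 2], [6, 3, 3]])
        normalize_log(ds)
        norm = ds.layers["normalized"].toarray()
        np.testing.assert_allclose(norm[0], np.log([3, 3, 5]))
        # median-libsize cell has scale factor exactly 1
        np.testing.assert_allclose(norm[1], np.log1p([4, 2, 2]))
        # monotone transform preserves within-cell gene ranking
        raw = ds.layers["counts"].toarray()
        for i in range(3):
            assert (np.argsort(norm[i]) == np.argsort(raw[i], kind="stable")).all()

    def test_zero_library_cell_rejected(self):
        ds = make_adata([[0, 0], [1, 2]])
        with pytest.raises(ValueError, match="zero-library"):
            normalize_log(ds)


class TestSelectHvg:
    def test_patterned_genes_rank_high(self, small_tissue):
        ds, model = small_tissue
        ds = ds.copy()
        hvg = select_hvg(ds, n_top=100)
        patterned = model.genes.index[model.genes["category"].isin(["ap", "ml", "both"])]
        frac = hvg.selected.loc[patterned].mean()
        assert frac >= 0.8  # 60 strongly patterned genes among the top 100

    def test_rare_gene_excluded_curated_retained(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(3, size=(40, 20))
        counts[:, 5] = 0
        counts[:5, 5] = 50  # huge variance but expressed in only 5 cells
        ds = make_adata(counts)
        hvg = select_hvg(ds, n_top=10)
        assert not hvg.selected.iloc[5]
        assert hvg.table["exclusion_reason"].iloc[5] == "rare"
        hvg2 = select_hvg(ds, n_top=10, curated=("g5",))
        assert hvg2.selected.loc["g5"]
        assert hvg2.table.loc["g5", "curated"]

    def test_mito_ribo_never_ranked(self):
        rng = np.random.default_rng(1)
        ds = make_adata(
            rng.poisson(5, size=(30, 4)), gene_ids=["mt-x", "Rps9", "a", "b"]
        )
        hvg = select_hvg(ds, n_top=2)
        assert not hvg.selected.loc["mt-x"]
        assert not hvg.selected.loc["Rps9"]


class TestRegressCellCycle:
    def _dataset_with_factor(self, amplitude):
        rng = np.random.default_rng(2)
        base = rng.poisson(10, size=(200, 30))
        ds = make_adata(base)
        normalize_log(ds)
        X = ds.layers["normalized"].toarray()
        factor = rng.normal(size=200)
        weights = np.zeros(30)
        weights[:8] = rng.uniform(0.5, 1.0, 8)  # cc genes g0..g7
        X = X + amplitude * np.outer(factor, weights)
        ds.layers["normalized"] = X
        cc = GeneSet("cc_phase", tuple(f"g{i}" for i in range(8)))
        return ds, factor, cc

    def test_planted_factor_removed(self):
        ds, factor, cc = self._dataset_with_factor(1.0)
        means = np.asarray(ds.layers["normalized"]).mean(axis=0).copy()
        regress_cell_cycle(ds, [cc])
        X = np.asarray(ds.layers["normalized"])
        corr = [
            abs(np.corrcoef(X[:, j], factor)[0, 1]) for j in range(8)
        ]
        assert max(corr) <= 0.05
        np.testing.assert_allclose(X.mean(axis=0), means, atol=1e-10)

    def test_constant_cc_program_leaves_layer_unchanged(self):
        # a cell-cycle program with no variation across cells is a no-op
        ds, _, cc = self._dataset_with_factor(0.0)
        X = np.asarray(ds.layers["normalized"])
        X[:, :8] = 1.7  # cc genes constant in every cell
        ds.layers["normalized"] = X
        before = X.copy()
        regress_cell_cycle(ds, [cc])
        np.testing.assert_allclose(
            np.asarray(ds.layers["normalized"]), before, atol=1e-10
        )

    def test_missing_genes_noop_with_warning(self, caplog):
        ds = make_adata(np.ones((20, 5), dtype=int) * 3)
        normalize_log(ds)
        before = ds.layers["normalized"].toarray().copy()
        with caplog.at_level("WARNING"):
            regress_cell_cycle(ds, [GeneSet("cc", ("Ghost1", "Ghost2"))])
        np.testing.assert_array_equal(ds.layers["normalized"].toarray(), before)


class TestPcaToVariance:
    def _factor_dataset(self, variances=(6.0, 3.0, 1.0), n=400, p=12, seed=3):
        rng = np.random.default_rng(seed)
        basis, _ = np.linalg.qr(rng.normal(size=(p, len(variances))))
        Z = rng.normal(size=(n, len(variances))) * np.sqrt(variances)
        X = Z @ basis.T + 1e-4 * rng.normal(size=(n, p))
        ds = make_adata(np.zeros((n, p), dtype=int))
        ds.layers["normalized"] = X
        return ds

    def test_component_count_from_eigenvalue_oracle(self):
        # generating variances 6, 3, 1: (6+3)/10 ≥ 0.75 ⇒ exactly 2 components
        ds = self._factor_dataset()
        coords = pca_to_variance(ds, target=0.75)
        assert coords.shape[1] == 2
        ratios = ds.uns["pca_variance_ratio"]
        assert (np.diff(ratios) <= 1e-12).all() and ratios.sum() <= 1 + 1e-9

    def test_target_one_keeps_all(self):
        ds = self._factor_dataset()
        coords = pca_to_variance(ds, target=1.0)
        assert coords.shape[1] == min(ds.shape) - 1 or coords.shape[1] == ds.n_vars

    def test_duplicate_cells_identical_coordinates(self):
        ds = self._factor_dataset(n=100)
        X = np.asarray(ds.layers["normalized"])
        X[1] = X[0]
        ds.layers["normalized"] = X
        coords = pca_to_variance(ds, target=0.9)
        np.testing.assert_allclose(coords[0], coords[1], atol=1e-8)


class TestKnnGraph:
    def test_line_geometry_with_tie_broken_by_index(self):
        coords = np.array([[0.0], [1.0], [2.0], [10.0]])
        idx, dist = exact_knn(coords, k=1)
        # point 1 is equidistant from 0 and 2: lower index wins
        assert idx.ravel().tolist() == [1, 0, 1, 2]
        g = knn_graph(coords, k=1, mode="unit")
        w = g.weights.toarray()
        assert w[np.arange(4), np.arange(4)].sum() == 0  # zero diagonal
        assert (w == w.T).all()
        assert set(zip(*np.nonzero(np.triu(w)))) == {(0, 1), (1, 2), (2, 3)}

    def test_adaptive_weights_positive_and_symmetric(self):
        rng = np.random.default_rng(4)
        g = knn_graph(rng.normal(size=(50, 3)), k=5, mode="adaptive_gaussian")
        assert g.symmetric
        assert (g.weights.data > 0).all() and (g.weights.data <= 1 + 1e-12).all()
        assert g.weights.diagonal().sum() == 0

    def test_k_too_large(self):
        with pytest.raises(ValueError, match="must be <"):
            knn_graph(np.zeros((5, 2)), k=5)
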