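import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from sklearn.metrics import rand_score

from neuralplate.classify import (
    AbsorptionClassifier,
    absorption_classify,
    assign_regions,
    build_training_labels,
    graph_cluster,
    signature_score,
)
from neuralplate.io import GeneSet, GeneSetError
from neuralplate.preprocess import NeighborGraph, knn_graph, normalize_log

from conftest import make_adata


def two_blobs(n=200, sep=20.0, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.normal(0, 1, size=(n, 5))
    b = rng.normal(0, 1, size=(n, 5))
    b[:, 0] += sep
    return np.vstack([a, b]), np.repeat([0, 1], n)


class TestGraphCluster:
    def test_separated_blobs_perfectly_split(self):
        coords, truth = two_blobs()
        labels = graph_cluster(knn_graph(coords, k=15, mode="unit"), seed=0)
        assert len(np.unique(labels)) == 2
        assert rand_score(truth, labels) == 1.0

    def test_rand_index_stable_across_k(self):
        coords, _ = two_blobs(seed=1)
        l1 = graph_cluster(knn_graph(coords, k=15, mode="unit"), seed=0)
        l2 = graph_cluster(knn_graph(coords, k=20, mode="unit"), seed=0)
        assert rand_score(l1, l2) > 0.8

    def test_labels_ordered_by_size(self):
        rng = np.random.default_rng(2)
        big = rng.normal(0, 1, size=(300, 3))
        small = rng.normal(30, 1, size=(60, 3))
        labels = graph_cluster(
            knn_graph(np.vstack([big, small]), k=10, mode="unit"), seed=0
        )
        counts = pd.Series(labels).value_counts()
        assert (counts.index.to_numpy() == np.arange(len(counts))).all()
        assert counts.is_monotonic_decreasing


class TestSignatureScore:
    def test_all_genes_positive_set_gives_zero(self):
        rng = np.random.default_rng(0)
        ds = make_adata(rng.poisson(4, size=(30, 12)))
        normalize_log(ds)
        gs = GeneSet("all", tuple(ds.var_names))
        np.testing.assert_allclose(signature_score(ds, gs), 0.0, atol=1e-12)

    def test_analytic_z_matches_monte_carlo_random_signatures(self):
        # the z-normalization claims mean/variance of a random same-size
        # signature; check against an explicit Monte-Carlo null per cell
        rng = np.random.default_rng(1)
        ds = make_adata(rng.poisson(3, size=(6, 400)))
        normalize_log(ds)
        X = ds.layers["normalized"].toarray()
        m = 15
        gs = GeneSet("sig", tuple(ds.var_names[:m]))
        analytic = signature_score(ds, gs)
        draws = np.array(
            [
                X[:, rng.choice(400, m, replace=False)].mean(axis=1)
                for _ in range(4000)
            ]
        )
        mc = (X[:, :m].mean(axis=1) - draws.mean(axis=0)) / draws.std(axis=0)
        np.testing.assert_allclose(analytic, mc, atol=0.25)

    def test_constant_shift_invariance_with_negatives(self):
        rng = np.random.default_rng(2)
        ds = make_adata(rng.poisson(4, size=(20, 30)))
        normalize_log(ds)
        gs = GeneSet("s", tuple(ds.var_names[:5]), tuple(ds.var_names[5:10]))
        s1 = signature_score(ds, gs)
        shifted = ds.copy()
        X = shifted.layers["normalized"].toarray() + 2.0  # same shift, all genes
        shifted.layers["normalized"] = X
        s2 = signature_score(shifted, gs)
        np.testing.assert_allclose(s1, s2, atol=1e-9)

    def test_planted_marker_program_separates_cells(self, small_tissue):
        ds, model = small_tissue
        ds = ds.copy()
        normalize_log(ds)
        fb = [gs for gs in model.region_gene_sets if gs.name == "forebrain"][0]
        z = signature_score(ds, fb)
        in_fb = (model.cells["region"] == "forebrain").to_numpy()
        thresh = np.quantile(z[~in_fb], 0.99)
        assert (z[in_fb] > thresh).mean() >= 0.95


class TestBuildTrainingLabels:
    def _scores(self):
        rng = np.random.default_rng(3)
        a = np.column_stack([rng.normal(3, 1, 100), rng.normal(-3, 1, 100)])
        b = np.column_stack([rng.normal(-3, 1, 100), rng.normal(3, 1, 100)])
        scores = pd.DataFrame(
            np.vstack([a, b]), columns=["T1", "T2"],
            index=[f"c{i}" for i in range(200)],
        )
        prelim = pd.Series(["T1"] * 100 + ["T2"] * 100, index=scores.index)
        return scores, prelim

    def test_separated_types_retain_most_cells(self):
        scores, prelim = self._scores()
        labels = build_training_labels(scores, prelim)
        for t in ("T1", "T2"):
            kept = (labels[prelim == t] == t).mean()
            assert kept >= 0.8  # only sub-20th-percentile own scores drop

    def test_cross_threshold_and_own_threshold_rules(self):
        scores, prelim = self._scores()
        # a cell above both thresholds and one below its own become unlabeled
        scores.iloc[0] = [10.0, 10.0]
        scores.iloc[1] = [-10.0, -10.0]
        labels = build_training_labels(scores, prelim)
        assert labels.iloc[0] == "" and labels.iloc[1] == ""

    def test_empty_type_errors(self):
        scores, prelim = self._scores()
        scores["T1"] = -100.0  # no cell can exceed its own threshold… all equal
        scores.iloc[: 100, 0] = np.linspace(0, 1, 100)  # own scores fine
        scores.iloc[100:, 0] = 50.0  # every T2 cell exceeds T1's threshold too
        scores.iloc[:100, 1] = 50.0  # and every T1 cell exceeds T2's
        with pytest.raises(ValueError, match="no surviving training"):
            build_training_labels(scores, prelim)


def dense_absorption_oracle(W, y):
    """Independent dense solve of the absorbing-chain equations."""
    W = np.asarray(W.todense() if sp.issparse(W) else W, dtype=float)
    P = W / W.sum(axis=1, keepdims=True)
    labels = sorted({v for v in y if v != -1})
    lab_idx = {c: j for j, c in enumerate(labels)}
    u = [i for i, v in enumerate(y) if v == -1]
    l = [i for i, v in enumerate(y) if v != -1]
    Q = P[np.ix_(u, u)]
    R = np.zeros((len(u), len(labels)))
    for col, i in enumerate(l):
        R[:, lab_idx[y[i]]] += P[np.ix_(u, [i])].ravel()
    B = np.linalg.solve(np.eye(len(u)) - Q, R)
    out = np.zeros((len(y), len(labels)))
    for i in l:
        out[i, lab_idx[y[i]]] = 1.0
    out[u] = B
    return out


class TestAbsorptionClassifier:
    def test_chain_absorption_probabilities_by_hand(self):
        # chain A–u1–u2–B with unit weights: u1 → (2/3, 1/3), u2 → (1/3, 2/3)
        W = sp.csr_matrix(
            np.array(
                [[0, 1, 0, 0], [1, 0, 1, 0], [0, 1, 0, 1], [0, 0, 1, 0]], float
            )
        )
        y = np.array(["A", -1, -1, "B"], dtype=object)
        clf = AbsorptionClassifier().fit(W, y)
        B = clf.label_distributions_
        np.testing.assert_allclose(B[1], [2 / 3, 1 / 3], atol=1e-10)
        np.testing.assert_allclose(B[2], [1 / 3, 2 / 3], atol=1e-10)

    def test_matches_dense_oracle_and_rows_sum_to_one(self):
        rng = np.random.default_rng(5)
        coords = rng.normal(size=(150, 4))
        W = knn_graph(coords, k=8, mode="adaptive_gaussian").weights
        y = np.full(150, -1, dtype=object)
        y[:10] = "A"
        y[10:20] = "B"
        clf = AbsorptionClassifier().fit(W, y)
        B = clf.label_distributions_
        np.testing.assert_allclose(B.sum(axis=1), 1.0, atol=1e-8)
        oracle = dense_absorption_oracle(W, y)
        np.testing.assert_allclose(B, oracle, atol=1e-6)

    def test_invariant_to_weight_rescaling(self):
        rng = np.random.default_rng(6)
        W = knn_graph(rng.normal(size=(60, 3)), k=5).weights
        y = np.full(60, -1, dtype=object)
        y[:5], y[5:10] = "A", "B"
        b1 = AbsorptionClassifier().fit(W, y).label_distributions_
        b2 = AbsorptionClassifier().fit(W * 7.3, y).label_distributions_
        np.testing.assert_allclose(b1, b2, atol=1e-10)

    def test_all_training_neighbors_one_step(self):
        W = sp.csr_matrix(np.array([[0, 1, 1], [1, 0, 0], [1, 0, 0]], float))
        y = np.array([-1, "A", "A"], dtype=object)
        clf = AbsorptionClassifier().fit(W, y)
        np.testing.assert_allclose(clf.label_distributions_[0], [1.0])


class TestAssignRegions:
    def test_missing_region_markers_error(self, small_tissue):
        ds, model = small_tissue
        ds = ds.copy()
        from neuralplate.pipeline import embed_dataset
        from neuralplate.config import PipelineConfig

        embed_dataset(ds, PipelineConfig(seed=0))
        sets = list(model.region_gene_sets)
        sets[0] = GeneSet("forebrain", ("Ghost1", "Ghost2"))
        with pytest.raises(GeneSetError, match="no usable positive"):
            assign_regions(ds, sets, k=15, seed=0)
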