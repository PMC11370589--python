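"""Graph clustering, signature scoring, and semi-supervised cell classification.

Cell types and neural-plate regions are assigned in four steps: (1) Leiden
community detection on a unit-weight kNN graph gives fine clusters; (2) each
cluster receives a preliminary label from its highest mean signature score;
(3) a high-confidence training set is carved out by the 20th-percentile rule —
a cell trains for its own type only if its own-type score exceeds that type's
20th percentile threshold while all other types' scores stay below theirs;
(4) the remaining cells are labeled by an absorbing Markov chain on the graph:
training cells are made absorbing and each unlabeled cell takes the label with
the highest absorption probability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData
from scipy.sparse.linalg import spsolve
from sklearn.base import BaseEstimator, ClassifierMixin

from .io import GeneSet, GeneSetError
from .preprocess import NeighborGraph, knn_graph

logger = logging.getLogger(__name__)


def _jaccard_graph(adjacency: sp.spmatrix) -> sp.csr_matrix:
    """Shared-neighbor (Jaccard) graph: w_ij = |N_i ∩ N_j| / |N_i ∪ N_j|.

    Connects every pair of cells sharing at least one neighbor, densifying
    communities into near-cliques so that modularity optimization recovers
    them whole instead of shattering sparse kNN communities.
    """
    A = (adjacency != 0).astype(np.float64).tocsr()
    inter = (A @ A.T).tocoo()
    sizes = np.asarray(A.sum(axis=1)).ravel()
    union = sizes[inter.row] + sizes[inter.col] - inter.data
    J = sp.coo_matrix(
        (inter.data / np.maximum(union, 1), (inter.row, inter.col)),
        shape=A.shape,
    ).tocsr()
    J.setdiag(0)
    J.eliminate_zeros()
    return J


def graph_cluster(g: NeighborGraph, seed: int = 0, resolution: float = 1.0) -> np.ndarray:
    """Seeded modularity (Leiden) community detection on a kNN graph.

    The kNN adjacency is first converted to a shared-neighbor Jaccard graph
    (the PhenoGraph-style construction); Leiden then maximizes weighted
    modularity on it.  Returns integer labels
    0..C-1 ordered by descending cluster size.  Isolated nodes become
    singleton clusters.
    """
    import igraph as ig
    import leidenalg

    w = sp.triu(_jaccard_graph(g.weights), k=1).tocoo()
    graph = ig.Graph(
        n=g.n_cells, edges=list(zip(w.row.tolist(), w.col.tolist())), directed=False
    )
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        weights=w.data.tolist(),
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=-1,
    )
    labels = np.asarray(part.membership)
    # relabel by descending size (ties by original label for determinism)
    sizes = pd.Series(labels).value_counts()
    order = sorted(sizes.index, key=lambda c: (-sizes[c], c))
    remap = {old: new for new, old in enumerate(order)}
    return np.asarray([remap[c] for c in labels])


def _dense_layer(adata: AnnData, layer: str = "normalized") -> np.ndarray:
    X = adata.layers[layer]
    return np.asarray(X.todense() if sp.issparse(X) else X, dtype=np.float64)


def signature_score(adata: AnnData, gs: GeneSet, layer: str = "normalized") -> np.ndarray:
    """Signed per-cell signature score, z-normalized against a random signature.

    Raw score s_c = mean expression over positive genes − mean over negative
    genes.  The null is a random signature of the same sizes drawn from the
    cell's gene-expression distribution (per-cell mean mu_c, variance v_c):
    with negatives, E[s] = 0 and Var[s] = v_c (1/m+ + 1/m−); with positives
    only, E[s] = mu_c and Var[s] = v_c / m+.
    """
    gs = gs.restrict(adata.var_names)
    X = _dense_layer(adata, layer)
    mu = X.mean(axis=1)
    v = X.var(axis=1)
    v = np.maximum(v, 1e-300)
    pos_idx = adata.var_names.get_indexer(list(gs.positive_genes))
    s = X[:, pos_idx].mean(axis=1)
    m_pos = len(gs.positive_genes)
    if gs.negative_genes:
        neg_idx = adata.var_names.get_indexer(list(gs.negative_genes))
        s = s - X[:, neg_idx].mean(axis=1)
        m_neg = len(gs.negative_genes)
        return s / np.sqrt(v * (1.0 / m_pos + 1.0 / m_neg))
    return (s - mu) / np.sqrt(v / m_pos)


@dataclass
class SignatureScores:
    scores: pd.DataFrame  # cells × signatures, NaN column when set unusable
    set_sizes: dict  # name -> (m_pos, m_neg) actually used

    @property
    def missing(self) -> list[str]:
        return [c for c in self.scores.columns if self.scores[c].isna().all()]


def score_gene_sets(adata: AnnData, gene_sets, layer: str = "normalized") -> SignatureScores:
    cols, sizes = {}, {}
    for gs in gene_sets:
        try:
            restricted = gs.restrict(adata.var_names)
            cols[gs.name] = signature_score(adata, restricted, layer)
            sizes[gs.name] = (len(restricted.positive_genes), len(restricted.negative_genes))
        except GeneSetError:
            logger.warning("signature %s: no usable positive genes; flagged missing", gs.name)
            cols[gs.name] = np.full(adata.n_obs, np.nan)
            sizes[gs.name] = (0, 0)
    return SignatureScores(pd.DataFrame(cols, index=adata.obs_names), sizes)


def build_training_labels(
    scores: pd.DataFrame, preliminary: pd.Series, percentile: float = 20.0
) -> pd.Series:
    """20th-percentile training-set construction.

    For each type t, theta_t is the ``percentile``-th percentile of t-scores
    among cells preliminarily labeled t.  A cell is a training example for its
    own type iff its own score exceeds theta_own and every other type's score
    is below that type's threshold; all other cells become unlabeled ("").
    """
    types = [t for t in scores.columns if (preliminary == t).any()]
    thresholds = {
        t: np.percentile(scores.loc[preliminary == t, t].dropna(), percentile)
        for t in types
    }
    labels = pd.Series("", index=scores.index, dtype=object)
    for t in types:
        own = (preliminary == t) & (scores[t] > thresholds[t])
        for other in types:
            if other != t:
                own &= scores[other] < thresholds[other]
        labels[own] = t
    empty = [t for t in types if not (labels == t).any()]
    if empty:
        raise ValueError(f"no surviving training cells for type(s): {empty}")
    return labels


class AbsorptionClassifier(BaseEstimator, ClassifierMixin):
    """Semi-supervised classification by absorbing Markov chain on a graph.

    Follows the scikit-learn LabelPropagation convention: ``fit(X, y)`` with
    ``y = -1`` marking unlabeled samples.  ``X`` is either a precomputed
    symmetric affinity matrix (``affinity="precomputed"``) or coordinates from
    which an adaptive-Gaussian kNN graph is built.

    The row-stochastic transition matrix P is taken from the graph weights;
    labeled cells are made absorbing, and for the unlabeled set U the
    absorption matrix solves (I − Q) B = R with Q = P[U, U], R = P[U, L],
    aggregated by label.  Assignment is the row argmax (ties broken by class
    order, with a warning).  Classification is invariant to graph weight
    rescaling because of the row normalization.

    Attributes
    ----------
    classes_ : ndarray of class labels
    label_distributions_ : (n_samples, n_classes) absorption probabilities
        (one-hot for training cells); rows sum to 1
    transduction_ : assigned label per sample
    """

    def __init__(self, affinity: str = "precomputed", k: int = 30, dense_max: int = 50000):
        self.affinity = affinity
        self.k = k
        self.dense_max = dense_max

    def fit(self, X, y):
        y = np.asarray(y, dtype=object)
        if self.affinity == "precomputed":
            W = sp.csr_matrix(X, dtype=np.float64)
        else:
            W = knn_graph(np.asarray(X, float), k=self.k, mode="adaptive_gaussian").weights
        n = W.shape[0]
        if len(y) != n:
            raise ValueError("y length does not match graph size")
        unlabeled = np.array([(v == -1) or (v is None) or (v == "") for v in y])
        labeled = ~unlabeled
        if not labeled.any():
            raise ValueError("need at least one labeled sample")
        self.classes_ = np.unique(y[labeled])

        deg = np.asarray(W.sum(axis=1)).ravel()
        deg = np.maximum(deg, 1e-300)
        P = sp.diags(1.0 / deg) @ W

        B = np.zeros((n, len(self.classes_)))
        class_index = {c: j for j, c in enumerate(self.classes_)}
        for i in np.flatnonzero(labeled):
            B[i, class_index[y[i]]] = 1.0

        u = np.flatnonzero(unlabeled)
        if u.size:
            l = np.flatnonzero(labeled)
            Q = P[u][:, u].tocsc()
            R = (P[u][:, l] @ B[l])  # n_u × n_classes
            A = (sp.identity(u.size, format="csc") - Q)
            sol = spsolve(A, sp.csc_matrix(R)) if u.size > 1 else np.atleast_2d(R / A[0, 0])
            sol = np.asarray(sol.todense() if sp.issparse(sol) else sol).reshape(
                u.size, len(self.classes_)
            )
            rowsum = sol.sum(axis=1)
            bad = ~np.isfinite(rowsum) | (rowsum < 1e-6)
            if bad.any():
                logger.warning(
                    "%d unlabeled cells unreachable from any training cell; uniform rows",
                    int(bad.sum()),
                )
                sol[bad] = 1.0 / len(self.classes_)
                rowsum[bad] = 1.0
            sol = sol / rowsum[:, None]
            B[u] = sol

        self.label_distributions_ = B
        best = B.argmax(axis=1)
        n_ties = int((np.isclose(B, B.max(axis=1, keepdims=True)).sum(axis=1) > 1).sum())
        if n_ties:
            logger.warning("%d cells with tied absorption; first class order wins", n_ties)
        self.transduction_ = self.classes_[best]
        self.training_mask_ = labeled
        return self

    def predict(self, X=None):
        return self.transduction_

    def predict_proba(self, X=None):
        return self.label_distributions_


@dataclass
class ClassifierResult:
    absorption: pd.DataFrame  # cells × labels
    assigned: pd.Series
    is_training: pd.Series


def absorption_classify(g: NeighborGraph, training_labels: pd.Series) -> ClassifierResult:
    """Run the absorbing-chain classifier on a neighbor graph."""
    clf = AbsorptionClassifier(affinity="precomputed").fit(
        g.weights, training_labels.to_numpy()
    )
    idx = training_labels.index
    return ClassifierResult(
        absorption=pd.DataFrame(clf.label_distributions_, index=idx, columns=clf.classes_),
        assigned=pd.Series(clf.transduction_, index=idx),
        is_training=pd.Series(clf.training_mask_, index=idx),
    )


def preliminary_labels_from_clusters(
    scores: pd.DataFrame, clusters: np.ndarray
) -> pd.Series:
    """Label each cluster by its maximum mean signature score (ties logged)."""
    prelim = pd.Series("", index=scores.index, dtype=object)
    for c in np.unique(clusters):
        members = clusters == c
        means = scores.loc[members].mean(axis=0)
        best = means.idxmax()
        ties = means.index[np.isclose(means, means.max())]
        if len(ties) > 1:
            logger.warning("cluster %d: tied signatures %s; taking %s", c, list(ties), best)
        prelim[members] = best
    return prelim


def assign_cell_types(
    adata: AnnData,
    gene_sets,
    k: int = 30,
    seed: int = 0,
    field: str = "cell_type",
) -> ClassifierResult:
    """Full typing loop: cluster → preliminary label → training set → absorption.

    Requires ``obsm["X_pca"]`` (run the embedding stage first).  Writes the
    assigned label into ``obs[field]``.
    """
    if "X_pca" not in adata.obsm:
        raise ValueError("run pca_to_variance before classification")
    coords = adata.obsm["X_pca"]
    unit = knn_graph(coords, k=k, mode="unit")
    sig = score_gene_sets(adata, gene_sets)
    if sig.missing:
        raise GeneSetError(
            f"signatures with no usable positive genes: {sig.missing}"
        )
    scores = sig.scores
    # preliminary labels come from *fine* clusters: the finest resolution on
    # the ladder at which every signature still dominates at least one cluster
    # (small populations need fine clusters to surface; contaminated coarse
    # clusters would poison the 20th-percentile training thresholds)
    best = None
    for resolution in (1.0, 2.0, 4.0, 8.0):
        clusters = graph_cluster(unit, seed=seed, resolution=resolution)
        prelim = preliminary_labels_from_clusters(scores, clusters)
        if set(prelim.unique()) >= set(scores.columns):
            best = (clusters, prelim, resolution)
    if best is None:
        raise ValueError(
            "no clustering resolution yields a cluster for every signature"
        )
    clusters, prelim, resolution = best
    logger.info("preliminary labels from clustering at resolution %.0f", resolution)
    adata.obs["cluster_id"] = clusters
    training = build_training_labels(scores, prelim)
    g = knn_graph(coords, k=k, mode="adaptive_gaussian")
    result = absorption_classify(g, training)
    adata.obs[field] = result.assigned.to_numpy()
    return result


def assign_regions(adata: AnnData, region_gene_sets, k: int = 30, seed: int = 0):
    """Assign neural-plate regions (forebrain, midbrain/r1, hindbrain, midline)."""
    return assign_cell_types(adata, region_gene_sets, k=k, seed=seed, field="region")
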