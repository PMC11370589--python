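"""Spatially patterned gene discovery along diffusion-derived latent spaces.

The selection statistic is a local autocorrelation: with symmetric kNN-graph
weights w_ij over a latent space (a single DC, or multiscale space) and
per-gene standardized expression x, H = Σ_{i≠j} w_ij x_i x_j.  Under the null
that expression is independent across cells, E[H] = 0 and, treating the
standardized values as i.i.d., Var[H] = 2 Σ_{i<j} w_ij², giving an analytic
z-score (a z-normalized Moran's I).  Genes pass selection when their
natural-log expression range exceeds 1, BH FDR < 1e-5, and Z ≥ 10 (or a
knee-point threshold computed on the sorted Z curve).

Selected genes are smoothed along an axis with MAGIC-style graph diffusion and
penalized cubic splines evaluated on 500 bins, clustered into per-axis trend
clusters, and — on the full 2-D catalogue — grouped into modules by Ward
hierarchical clustering of the gene–gene correlation matrix with a knee-point
default cut.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData
from scipy import stats
from scipy.cluster.hierarchy import fcluster, ward
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .classify import graph_cluster, signature_score
from .io import GeneSet
from .preprocess import NeighborGraph, knn_graph

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# local autocorrelation


def _autocorr_weights(latent: np.ndarray, k: int = 30) -> sp.csr_matrix:
    """Adaptive-Gaussian kNN weights, row-normalized then re-symmetrized."""
    g = knn_graph(latent, k=k, mode="adaptive_gaussian")
    W = g.weights
    deg = np.asarray(W.sum(axis=1)).ravel()
    W = sp.diags(1.0 / np.maximum(deg, 1e-300)) @ W
    W = (W + W.T) * 0.5
    W = W.tocsr()
    W.setdiag(0)
    W.eliminate_zeros()
    return W


def local_autocorrelation(
    adata: AnnData, latent: np.ndarray, k: int = 30, layer: str = "normalized"
) -> pd.DataFrame:
    """Per-gene autocorrelation H, z-score, p, BH FDR and expression range.

    With standardized expression x (mean 0, variance 1), H = Σ_{i≠j} w_ij
    x_i x_j equals S0 · I where I is Moran's I and S0 = Σ_{i≠j} w_ij, so the
    null moments under random assignment of values to cells are the classical
    randomization moments of Moran's I: E[H] = −S0/(n−1) and Var[H] from the
    S1/S2/kurtosis formula.  (The cruder i.i.d. approximation Var[H] =
    2 Σ_{i<j} w_ij² ignores the permutation constraints and is biased by tens
    of percent at n ≈ 300 — outside the permutation-oracle tolerance the
    tests enforce.)  Constant genes get Z = 0, p = 1 by convention.  The
    expression input is the log-normalized (never the imputed) layer.
    """
    latent = np.asarray(latent, float)
    if latent.ndim == 1:
        latent = latent[:, None]
    if latent.shape[0] != adata.n_obs:
        raise ValueError("latent rows do not match dataset cells")
    W = _autocorr_weights(latent, k=k)
    n = W.shape[0]

    # randomization-null moments of Moran's I (symmetric W, zero diagonal)
    s0 = W.sum()
    s1 = 2.0 * np.sum(W.data**2)  # ½ Σ (w_ij + w_ji)² = 2 Σ w_ij²
    row = np.asarray(W.sum(axis=1)).ravel()
    s2 = np.sum((2.0 * row) ** 2)

    X = adata.layers[layer]
    X = np.asarray(X.todense() if sp.issparse(X) else X, dtype=np.float64)
    rng_ln = X.max(axis=0) - X.min(axis=0)
    sd = X.std(axis=0)
    const = sd == 0
    Xz = (X - X.mean(axis=0)) / np.where(const, 1.0, sd)
    H = np.einsum("ij,ij->j", Xz, W @ Xz)

    b2 = (Xz**4).mean(axis=0)  # per-gene kurtosis of the standardized values
    e_i = -1.0 / (n - 1)
    num_a = n * ((n * n - 3 * n + 3) * s1 - n * s2 + 3 * s0 * s0)
    num_b = (n * n - n) * s1 - 2 * n * s2 + 6 * s0 * s0
    denom = (n - 1) * (n - 2) * (n - 3) * s0 * s0
    var_i = (num_a - b2 * num_b) / denom - e_i**2
    var_h = np.maximum(var_i, 1e-300) * s0 * s0

    Z = (H - s0 * e_i) / np.sqrt(var_h)
    Z[const] = 0.0
    p = stats.norm.sf(Z)
    p[const] = 1.0
    fdr = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {"H": np.where(const, np.nan, H), "Z": Z, "p": p, "fdr": fdr, "range": rng_ln},
        index=adata.var_names,
    )


def knee_point(curve) -> int:
    """Index of maximum perpendicular distance to the first–last chord.

    Ties return the smallest index; an exactly straight curve returns 0 with
    a warning.
    """
    y = np.asarray(curve, float)
    if y.size < 3:
        raise ValueError("need at least 3 points")
    x = np.arange(y.size, dtype=float)
    dx, dy = x[-1] - x[0], y[-1] - y[0]
    norm = np.hypot(dx, dy)
    dist = np.abs(dy * (x - x[0]) - dx * (y - y[0])) / max(norm, 1e-300)
    if np.allclose(dist, 0):
        logger.warning("curve is a straight line; knee undefined, returning 0")
        return 0
    return int(np.argmax(dist))


def select_spatial_genes(
    result: pd.DataFrame,
    fdr_max: float = 1e-5,
    z_min: float | str = 10.0,
    range_min: float = 1.0,
) -> list[str]:
    """Apply the range / FDR / Z filters; returns genes sorted by Z descending.

    ``z_min`` is either a fixed threshold or the string ``"knee"``, in which
    case the threshold is the knee point of the descending sorted Z curve over
    all genes.  An empty selection is valid (logged).
    """
    if z_min == "knee":
        z_sorted = np.sort(result["Z"].to_numpy())[::-1]
        z_thr = float(z_sorted[knee_point(z_sorted)])
        logger.info("knee-point Z threshold: %.2f", z_thr)
    else:
        z_thr = float(z_min)
    keep = (result["range"] > range_min) & (result["fdr"] < fdr_max) & (result["Z"] >= z_thr)
    result = result.assign(selected=keep)
    genes = result.loc[keep].sort_values("Z", ascending=False).index.tolist()
    if not genes:
        logger.info("no genes passed spatial selection")
    return genes


class SpatialAutocorrelation(BaseEstimator):
    """Feature selector flagging genes autocorrelated along a latent space.

    ``fit(X, y=None, latent=...)`` takes the cells × genes expression matrix
    and the latent coordinates; ``get_support()`` returns the boolean mask of
    selected genes, matching the scikit-learn selector idiom.
    """

    def __init__(
        self,
        k: int = 30,
        fdr_max: float = 1e-5,
        z_min: float | str = 10.0,
        range_min: float = 1.0,
    ):
        self.k = k
        self.fdr_max = fdr_max
        self.z_min = z_min
        self.range_min = range_min

    def fit(self, X, y=None, *, latent):
        X = np.asarray(X, float)
        tmp = AnnData(
            X=sp.csr_matrix(X.shape, dtype=np.float64),
            obs=pd.DataFrame(index=[f"c{i}" for i in range(X.shape[0])]),
            var=pd.DataFrame(index=[f"g{j}" for j in range(X.shape[1])]),
        )
        tmp.layers["normalized"] = X
        self.result_ = local_autocorrelation(tmp, latent, k=self.k)
        sel = select_spatial_genes(
            self.result_, fdr_max=self.fdr_max, z_min=self.z_min, range_min=self.range_min
        )
        self.support_ = self.result_.index.isin(sel)
        self.zscores_ = self.result_["Z"].to_numpy()
        return self

    def get_support(self) -> np.ndarray:
        return self.support_


# ---------------------------------------------------------------------------
# imputation and trends


class GraphDiffusionImputer(BaseEstimator):
    """MAGIC-style smoothing: imputed = (D⁻¹W)ᵗ · expression with k=5, t=3.

    Fitted on latent coordinates (the space defining cell–cell similarity);
    ``transform`` smooths any cells × genes matrix.  Imputed values are for
    trends and display only, never for statistics.
    """

    def __init__(self, k: int = 5, t: int = 3):
        self.k = k
        self.t = t

    def fit(self, X, y=None):
        g = knn_graph(np.asarray(X, float), k=self.k, mode="adaptive_gaussian")
        W = g.weights
        deg = np.asarray(W.sum(axis=1)).ravel()
        self.transition_ = sp.diags(1.0 / np.maximum(deg, 1e-300)) @ W
        return self

    def transform(self, expr) -> np.ndarray:
        out = np.asarray(
            expr.todense() if sp.issparse(expr) else expr, dtype=np.float64
        ).copy()
        for _ in range(self.t):
            out = self.transition_ @ out
        return out


def impute(adata: AnnData, latent: np.ndarray, k: int = 5, t: int = 3) -> AnnData:
    """Add ``layers["imputed"]`` by graph diffusion over the latent space."""
    imp = GraphDiffusionImputer(k=k, t=t).fit(latent)
    adata.layers["imputed"] = imp.transform(adata.layers["normalized"])
    return adata


@dataclass
class TrendSet:
    trends: pd.DataFrame  # genes × n_bins fitted values
    axis_grid: np.ndarray  # n_bins axis positions (equally spaced min→max)
    clusters: pd.Series | None = None


def _bspline_design(x: np.ndarray, knots_inner: np.ndarray, degree: int = 3):
    from scipy.interpolate import BSpline

    lo, hi = knots_inner[0], knots_inner[-1]
    t = np.r_[[lo] * degree, knots_inner, [hi] * degree]
    n_basis = len(t) - degree - 1
    B = np.empty((x.size, n_basis))
    xc = np.clip(x, lo, hi)
    for j in range(n_basis):
        c = np.zeros(n_basis)
        c[j] = 1.0
        B[:, j] = BSpline(t, c, degree)(xc)
    return B


def fit_trends(
    adata: AnnData,
    axis: np.ndarray,
    genes,
    n_bins: int = 500,
    n_knots: int = 8,
    layer: str = "imputed",
    lambdas: np.ndarray | None = None,
) -> TrendSet:
    """Penalized cubic-spline expression trends along an axis.

    Per gene, imputed expression is regressed on a cubic B-spline basis with
    ``n_knots`` knots at axis quantiles and a second-difference penalty; the
    penalty weight is chosen per gene by generalized cross-validation over a
    fixed log-spaced grid.  Predictions are evaluated at ``n_bins`` equally
    spaced axis values between the axis minimum and maximum.
    """
    axis = np.asarray(axis, float)
    ok = np.isfinite(axis)
    if ok.sum() < 50:
        raise ValueError("need at least 50 cells with finite axis values")
    genes = list(genes)
    X = adata.layers[layer]
    X = np.asarray(X.todense() if sp.issparse(X) else X, dtype=np.float64)
    cols = adata.var_names.get_indexer(genes)
    if (cols < 0).any():
        missing = [g for g, c in zip(genes, cols) if c < 0]
        raise KeyError(f"genes absent from dataset: {missing[:5]}")
    Y = X[np.ix_(ok, cols)]
    x = axis[ok]

    knots = np.unique(np.quantile(x, np.linspace(0, 1, n_knots)))
    if knots.size < 4:  # nearly constant axis: pad
        knots = np.linspace(x.min(), x.max() + 1e-9, 4)
    B = _bspline_design(x, knots)
    nb = B.shape[1]
    D = np.diff(np.eye(nb), n=2, axis=0)
    P = D.T @ D
    BtB, BtY = B.T @ B, B.T @ Y
    if lambdas is None:
        lambdas = np.logspace(-4, 6, 21)

    n = x.size
    gcv = np.empty((len(lambdas), len(genes)))
    betas = np.empty((len(lambdas), nb, len(genes)))
    for i, lam in enumerate(lambdas):
        A = BtB + lam * P
        Ainv = np.linalg.inv(A)
        beta = Ainv @ BtY
        betas[i] = beta
        edf = np.trace(Ainv @ BtB)
        rss = np.sum((Y - B @ beta) ** 2, axis=0)
        gcv[i] = n * rss / (n - edf) ** 2
    best = gcv.argmin(axis=0)

    grid = np.linspace(x.min(), x.max(), n_bins)
    Bg = _bspline_design(grid, knots)
    fitted = np.empty((len(genes), n_bins))
    for j in range(len(genes)):
        fitted[j] = Bg @ betas[best[j], :, j]
    return TrendSet(pd.DataFrame(fitted, index=pd.Index(genes)), grid)


def cluster_trends(ts: TrendSet, k: int = 20, seed: int = 0) -> pd.Series:
    """Cluster z-normalized trends on a kNN graph; labels ordered by peak.

    Labels are integers 0..C−1 ordered by the mean axis position of each
    cluster's trend peaks, so anterior-peaked clusters precede posterior ones.
    """
    T = ts.trends.to_numpy()
    if T.shape[0] < k + 1:
        raise ValueError(f"need more than k={k} genes to cluster trends; try smaller k")
    sd = T.std(axis=1, keepdims=True)
    Tz = (T - T.mean(axis=1, keepdims=True)) / np.where(sd == 0, 1.0, sd)
    if np.allclose(Tz, Tz[0]):  # degenerate: all trends identical
        labels = pd.Series(0, index=ts.trends.index, name="trend_cluster")
        ts.clusters = labels
        return labels
    g = knn_graph(Tz, k=k, mode="unit")
    raw = graph_cluster(g, seed=seed)
    peak = T.argmax(axis=1)
    order = sorted(np.unique(raw), key=lambda c: (peak[raw == c].mean(), c))
    remap = {old: new for new, old in enumerate(order)}
    labels = pd.Series([remap[c] for c in raw], index=ts.trends.index, name="trend_cluster")
    ts.clusters = labels
    return labels


# ---------------------------------------------------------------------------
# multiscale gene modules


@dataclass
class ModuleHierarchy:
    linkage: np.ndarray
    genes: pd.Index
    labels_at_distance: dict  # D -> Series of labels
    default_n_clusters: int
    default_labels: pd.Series
    mean_intra_corr: dict  # n_clusters -> mean within-cluster pairwise r (knee curve)
    median_intra_corr: dict  # n_clusters -> median within-cluster pairwise r
    correlation: pd.DataFrame = field(repr=False, default=None)


def _intra_cluster_pairs(corr: np.ndarray, labels: np.ndarray) -> np.ndarray:
    vals = []
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        if idx.size > 1:
            sub = corr[np.ix_(idx, idx)]
            vals.append(sub[np.triu_indices(idx.size, k=1)])
    return np.concatenate(vals) if vals else np.array([np.nan])


def module_hierarchy(
    adata: AnnData,
    genes,
    cut_distances=(10.0, 6.0, 4.0),
    layer: str = "normalized",
    max_clusters: int = 30,
) -> ModuleHierarchy:
    """Ward clustering of genes on rows of their Pearson correlation matrix.

    Each gene's feature vector is its row of the gene–gene correlation matrix
    (computed on the log-normalized layer); Ward linkage on Euclidean
    distances yields a hierarchy cut at the requested absolute distances and
    at a default data-driven cut: the knee point of the within-cluster
    pairwise correlation as a function of cluster count.  The knee curve uses
    the MEAN within-cluster pairwise correlation — the average similarity of
    genes sharing a cluster, which under-merged cuts dilute with cross-module
    pairs; the median is insensitive to that dilution below 50% contamination
    and is reported per cut but not used for the knee.
    """
    genes = list(genes)
    if len(genes) < 3:
        raise ValueError("need at least 3 genes for module discovery")
    X = adata.layers[layer]
    X = np.asarray(X.todense() if sp.issparse(X) else X, dtype=np.float64)
    cols = adata.var_names.get_indexer(genes)
    Y = X[:, cols]
    sd = Y.std(axis=0)
    const = sd == 0
    if const.any():
        logger.warning("dropping %d constant genes from module discovery", const.sum())
        keep = ~const
        genes = [g for g, k_ in zip(genes, keep) if k_]
        Y, sd = Y[:, keep], sd[keep]
    Yz = (Y - Y.mean(axis=0)) / sd
    corr = (Yz.T @ Yz) / Y.shape[0]
    np.clip(corr, -1, 1, out=corr)

    Z = ward(corr)  # Euclidean distances between correlation-matrix rows
    gene_index = pd.Index(genes)
    labels_at = {
        float(D): pd.Series(fcluster(Z, t=D, criterion="distance") - 1, index=gene_index)
        for D in cut_distances
    }

    n_max = min(max_clusters, len(genes))
    counts = np.arange(1, n_max + 1)
    pairs = [
        _intra_cluster_pairs(corr, fcluster(Z, t=c, criterion="maxclust"))
        for c in counts
    ]
    mean_curve = np.array([float(np.mean(v)) for v in pairs])
    median_curve = np.array([float(np.median(v)) for v in pairs])
    default_n = int(counts[knee_point(mean_curve)])
    default_labels = pd.Series(
        fcluster(Z, t=default_n, criterion="maxclust") - 1, index=gene_index
    )
    return ModuleHierarchy(
        linkage=Z,
        genes=gene_index,
        labels_at_distance=labels_at,
        default_n_clusters=default_n,
        default_labels=default_labels,
        mean_intra_corr=dict(zip(counts.tolist(), mean_curve.tolist())),
        median_intra_corr=dict(zip(counts.tolist(), median_curve.tolist())),
        correlation=pd.DataFrame(corr, index=gene_index, columns=gene_index),
    )


def module_cell_scores(
    adata: AnnData, labels: pd.Series, layer: str = "normalized"
) -> pd.DataFrame:
    """Per-cell module scores: signature score of each module's gene list."""
    out = {}
    for c in sorted(labels.unique()):
        gs = GeneSet(f"module_{c}", tuple(labels.index[labels == c]))
        out[gs.name] = signature_score(adata, gs, layer=layer)
    return pd.DataFrame(out, index=adata.obs_names)
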