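"""Normalization, feature selection, cell-cycle regression, PCA, kNN graphs.

Normalization is median-library-size scaling followed by ln(x + 1); it is
sample-set dependent (the median changes with the cell set), so it is
recomputed after every subset, matching the per-region reprocessing of the
analysis.  HVG ranking uses the variance-stabilizing transform: a quadratic
mean–variance trend in log10 space, standardized values clipped at sqrt(n),
and the variance of the clipped values as the ranking statistic.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData

logger = logging.getLogger(__name__)


@dataclass
class NeighborGraph:
    """Symmetric cell × cell kNN graph (zero diagonal)."""

    weights: sp.csr_matrix
    k: int
    mode: str  # "unit" or "adaptive_gaussian"

    @property
    def n_cells(self) -> int:
        return self.weights.shape[0]

    @property
    def symmetric(self) -> bool:
        return (abs(self.weights - self.weights.T) > 1e-12).nnz == 0


@dataclass
class HVGResult:
    table: pd.DataFrame  # standardized_variance, selected, exclusion_reason, curated

    @property
    def selected(self) -> pd.Series:
        return self.table["selected"]


def normalize_log(adata: AnnData) -> AnnData:
    """Median-library normalization then natural log with pseudocount 1.

    Adds ``layers["normalized"]`` = ln(1 + counts * median(libsize)/libsize).
    """
    counts = sp.csr_matrix(adata.layers["counts"], dtype=np.float64)
    libsize = np.asarray(counts.sum(axis=1)).ravel()
    if np.any(libsize == 0):
        raise ValueError("zero-library cell encountered; run QC first")
    scale = np.median(libsize) / libsize
    norm = sp.diags(scale) @ counts
    norm.data = np.log1p(norm.data)
    adata.layers["normalized"] = norm.tocsr()
    return adata


# backwards-compatible alias used in a few call sites
log_normalize = normalize_log


def _vst_standardized_variance(counts: sp.csc_matrix) -> np.ndarray:
    """Per-gene variance of clipped standardized counts (vst ranking)."""
    n = counts.shape[0]
    mean = np.asarray(counts.mean(axis=0)).ravel()
    sq = counts.copy()
    sq.data = sq.data**2
    var = np.asarray(sq.mean(axis=0)).ravel() - mean**2
    var *= n / max(n - 1, 1)

    out = np.zeros(counts.shape[1])
    ok = (mean > 0) & (var > 0)
    if ok.sum() < 3:
        return out
    # quadratic trend of log10 variance on log10 mean (loess stand-in)
    lx, ly = np.log10(mean[ok]), np.log10(var[ok])
    coef = np.polyfit(lx, ly, deg=2)
    sd_pred = np.sqrt(10 ** np.polyval(coef, np.log10(mean[ok])))
    clip = math.sqrt(n)

    idx = np.flatnonzero(ok)
    csc = counts.tocsc()
    for pos, j in enumerate(idx):
        x = csc.data[csc.indptr[j] : csc.indptr[j + 1]]
        mu, sd = mean[j], sd_pred[pos]
        z_nz = np.clip((x - mu) / sd, -clip, clip)
        z_zero = np.clip(-mu / sd, -clip, clip)
        n_zero = n - x.size
        out[j] = (np.sum(z_nz**2) + n_zero * z_zero**2) / (n - 1)
    return out


def select_hvg(
    adata: AnnData, n_top: int = 3000, curated: tuple[str, ...] = ()
) -> HVGResult:
    """Rank genes by vst standardized variance and select the top ``n_top``.

    Mitochondrial and ribosomal genes and genes expressed in fewer than 10
    cells are excluded from the ranking; curated marker genes are force-
    retained regardless of variance and flagged.
    """
    counts = sp.csc_matrix(adata.layers["counts"], dtype=np.float64)
    svar = _vst_standardized_variance(counts)

    reason = pd.Series("none", index=adata.var_names, dtype=object)
    reason[adata.var["n_cells_expressing"].to_numpy() < 10] = "rare"
    reason[adata.var["is_ribo"].to_numpy()] = "ribo"
    reason[adata.var["is_mito"].to_numpy()] = "mito"
    eligible = reason == "none"

    n_eligible = int(eligible.sum())
    if n_top >= n_eligible:
        logger.warning("n_top=%d >= %d eligible genes; selecting all", n_top, n_eligible)
    order = np.argsort(svar)[::-1]
    selected = np.zeros(adata.n_vars, dtype=bool)
    picked = 0
    for j in order:
        if picked >= n_top:
            break
        if eligible.iloc[j]:
            selected[j] = True
            picked += 1
    curated_flag = adata.var_names.isin(curated)
    selected |= curated_flag

    table = pd.DataFrame(
        {
            "standardized_variance": svar,
            "selected": selected,
            "exclusion_reason": reason,
            "curated": curated_flag,
        },
        index=adata.var_names,
    )
    adata.var["highly_variable"] = selected
    return HVGResult(table)


def regress_cell_cycle(adata: AnnData, cc_sets) -> AnnData:
    """Residualize the normalized layer on per-cell cell-cycle scores.

    Each gene's normalized expression is regressed (OLS) on the mean
    expression of each cell-cycle gene set (the raw signature score — linear
    in any additive cell-cycle factor, so the regression removes it exactly
    in the noiseless limit; the z-normalized score is nonlinear through the
    per-cell variance and would leave a residual component).  Residuals are
    re-centered so the per-gene mean is preserved.  No usable cell-cycle
    genes → no-op + warning.
    """
    from .io import GeneSetError

    scores = []
    for gs in cc_sets:
        try:
            gs = gs.restrict(adata.var_names)
        except GeneSetError:
            logger.warning("cell-cycle set %s has no genes in dataset; skipped", gs.name)
            continue
        layer = adata.layers["normalized"]
        idx = adata.var_names.get_indexer(list(gs.positive_genes))
        s = np.asarray(layer[:, idx].mean(axis=1)).ravel()
        if gs.negative_genes:
            neg = adata.var_names.get_indexer(list(gs.negative_genes))
            s = s - np.asarray(layer[:, neg].mean(axis=1)).ravel()
        if s.std() == 0:
            logger.warning("cell-cycle set %s has constant score; skipped", gs.name)
            continue
        scores.append(s)
    if not scores:
        logger.warning("no cell-cycle genes present; normalized layer unchanged")
        return adata
    S = np.column_stack(scores)
    X = np.asarray(
        adata.layers["normalized"].todense()
        if sp.issparse(adata.layers["normalized"])
        else adata.layers["normalized"],
        dtype=np.float64,
    )
    design = np.column_stack([np.ones(adata.n_obs), S])
    beta, *_ = np.linalg.lstsq(design, X, rcond=None)
    resid = X - design @ beta
    resid += X.mean(axis=0, keepdims=True) - resid.mean(axis=0, keepdims=True)
    adata.layers["normalized"] = resid
    return adata


def pca_to_variance(
    adata: AnnData,
    target: float = 0.75,
    hvg_mask=None,
    seed: int = 0,
    max_components: int = 100,
) -> np.ndarray:
    """PCA on the (gene-centered) normalized HVG matrix.

    The number of components retained is the smallest m whose cumulative
    explained-variance ratio reaches ``target``.  Exact SVD below 5,000 cells;
    seeded randomized SVD above.  Stores ``obsm["X_pca"]`` and
    ``uns["pca_variance_ratio"]``.
    """
    from sklearn.decomposition import PCA

    if adata.n_obs < 2:
        raise ValueError("PCA needs at least 2 cells")
    layer = adata.layers["normalized"]
    if hvg_mask is None and "highly_variable" in adata.var:
        hvg_mask = adata.var["highly_variable"].to_numpy()
    X = layer[:, hvg_mask] if hvg_mask is not None else layer
    X = np.asarray(X.todense() if sp.issparse(X) else X, dtype=np.float64)

    max_m = min(X.shape[0], X.shape[1]) - 1
    max_m = max(max_m, 1)
    if adata.n_obs < 5000:
        pca = PCA(n_components=min(max_m, X.shape[1]), svd_solver="full")
    else:
        pca = PCA(
            n_components=min(max_components, max_m),
            svd_solver="randomized",
            random_state=seed,
        )
    coords = pca.fit_transform(X)
    ratios = pca.explained_variance_ratio_
    cum = np.cumsum(ratios)
    if target >= cum[-1]:
        m = len(ratios)
    else:
        m = int(np.searchsorted(cum, target) + 1)
    coords = coords[:, :m]
    adata.obsm["X_pca"] = coords
    adata.uns["pca_variance_ratio"] = ratios[:m]
    return coords


def exact_knn(coords: np.ndarray, k: int, chunk: int = 1024):
    """Deterministic exact k-nearest neighbors (ties broken by lower index).

    Returns (indices, distances), each n × k, excluding self.
    """
    n = coords.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be < n_cells={n}")
    idx_out = np.empty((n, k), dtype=np.int64)
    dist_out = np.empty((n, k))
    sq = np.einsum("ij,ij->i", coords, coords)
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        d2 = sq[start:stop, None] + sq[None, :] - 2 * coords[start:stop] @ coords.T
        np.maximum(d2, 0, out=d2)
        rows = np.arange(start, stop)
        d2[np.arange(stop - start), rows] = np.inf  # exclude self
        for i in range(stop - start):
            order = np.lexsort((np.arange(n), d2[i]))[:k]
            idx_out[start + i] = order
            dist_out[start + i] = np.sqrt(d2[i][order])
    return idx_out, dist_out


def knn_graph(coords: np.ndarray, k: int = 30, mode: str = "adaptive_gaussian") -> NeighborGraph:
    """Build a symmetric kNN graph over Euclidean coordinates.

    ``unit`` weights (0/1) serve community detection; ``adaptive_gaussian``
    weights exp(-d^2 / sigma_i^2) with sigma_i the distance to the
    ceil(k/3)-th neighbor serve diffusion maps and autocorrelation.
    Symmetrized by the elementwise maximum of w_ij and w_ji.
    """
    coords = np.asarray(coords, dtype=np.float64)
    if coords.ndim == 1:
        coords = coords[:, None]
    n = coords.shape[0]
    idx, dist = exact_knn(coords, k)
    rows = np.repeat(np.arange(n), k)
    cols = idx.ravel()
    if mode == "unit":
        data = np.ones(n * k)
    elif mode == "adaptive_gaussian":
        sigma = dist[:, max(math.ceil(k / 3) - 1, 0)]
        sigma = np.maximum(sigma, 1e-12)
        data = np.exp(-((dist / sigma[:, None]) ** 2)).ravel()
    else:
        raise ValueError(f"unknown mode {mode!r}")
    w = sp.csr_matrix((data, (rows, cols)), shape=(n, n))
    w = w.maximum(w.T)
    w.setdiag(0)
    w.eliminate_zeros()
    return NeighborGraph(w.tocsr(), k=k, mode=mode)
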