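"""Diffusion maps, eigengap component selection, multiscale space, DC–gene tables.

The cell–cell Markov matrix M = D⁻¹W is built from an adaptive-Gaussian kNN
graph; its non-stationary right eigenvectors, ordered by descending eigenvalue
and labeled DC0, DC1, …, are smooth axes of variation.  On the late-stage
pooled neural plate the anterior–posterior axis appears as one leading DC and
the mediolateral axis as another; which DC matches which axis is established
by correlation with marker gene sets, not assumed.  Within a single region,
DC0 tracks developmental stage and serves as the temporal axis.  Multiscale
space rescales each component by λ/(1−λ), giving a Euclidean-friendly
embedding of the top components.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData
from scipy import stats
from sklearn.base import BaseEstimator

from .preprocess import NeighborGraph, knn_graph

logger = logging.getLogger(__name__)


@dataclass
class DiffusionResult:
    coordinates: np.ndarray  # cells × components (NaN off the giant component)
    eigenvalues: np.ndarray  # descending, stationary eigenvalue removed
    n_selected: int  # eigengap rule

    @property
    def component_labels(self) -> list[str]:
        return [f"DC{i}" for i in range(self.coordinates.shape[1])]

    def multiscale(self, n: int | None = None) -> np.ndarray:
        return multiscale_embed(self, self.n_selected if n is None else n)


def select_eigengap(eigenvalues: np.ndarray, search_window: int = 40) -> int:
    """Number of components preceding the largest eigengap.

    Scans gaps λ_i − λ_{i+1} within the first ``search_window`` eigenvalues
    (descending order, stationary removed) and returns the count of components
    kept.  Ties go to the smallest count.
    """
    lam = np.asarray(eigenvalues, float)
    if lam.size < 3:
        raise ValueError("need at least 3 eigenvalues for eigengap selection")
    gaps = lam[:-1] - lam[1:]
    gaps = gaps[: max(min(search_window, lam.size) - 1, 1)]
    n = int(np.argmax(gaps)) + 1  # first maximal gap
    if (np.isclose(gaps, gaps.max())).sum() > 1:
        logger.warning("tied eigengaps; selecting the smallest count %d", n)
    return n


def multiscale_embed(dr: DiffusionResult, n: int) -> np.ndarray:
    """Multiscale coordinates: DC_i × λ_i/(1−λ_i) for the top n components."""
    if n <= 0:
        raise ValueError("n must be positive")
    if n > dr.coordinates.shape[1]:
        raise ValueError(f"n={n} exceeds {dr.coordinates.shape[1]} available components")
    lam = dr.eigenvalues[:n]
    if np.any(lam >= 1):
        raise ValueError("stationary eigenvalue present; remove before scaling")
    return dr.coordinates[:, :n] * (lam / (1 - lam))[None, :]


class DiffusionMapEmbedding(BaseEstimator):
    """Diffusion-map transformer over an adaptive-Gaussian kNN graph.

    Parameters
    ----------
    n_components : eigenpairs to compute (before eigengap selection)
    k : neighbors for the graph when fitting from coordinates
    density_normalize : if True, apply anisotropic density normalization
        (divide W by the degree outer product, alpha = 1) before the Markov
        normalization; off by default
    eigengap_window : window for the component-count rule

    Attributes (after fit)
    ----------------------
    embedding_ : cells × n_components diffusion coordinates
    eigenvalues_ : descending, stationary removed
    n_selected_ : eigengap-selected component count
    """

    def __init__(
        self,
        n_components: int = 40,
        k: int = 30,
        density_normalize: bool = False,
        eigengap_window: int = 40,
    ):
        self.n_components = n_components
        self.k = k
        self.density_normalize = density_normalize
        self.eigengap_window = eigengap_window

    def fit(self, X, y=None):
        if isinstance(X, NeighborGraph):
            W = X.weights
        elif sp.issparse(X):
            W = sp.csr_matrix(X, dtype=np.float64)
        else:
            W = knn_graph(np.asarray(X, float), k=self.k, mode="adaptive_gaussian").weights
        n = W.shape[0]
        if (W != W.T).nnz:
            raise ValueError("graph weights must be symmetric")
        if self.density_normalize:
            deg = np.asarray(W.sum(axis=1)).ravel()
            inv = sp.diags(1.0 / np.maximum(deg, 1e-300))
            W = inv @ W @ inv

        n_comp, comps = sp.csgraph.connected_components(W, directed=False)
        if n_comp > 1:
            sizes = np.bincount(comps)
            giant = int(np.argmax(sizes))
            logger.warning(
                "graph has %d components; diffusion computed on the giant "
                "component (%d/%d cells), others get NaN coordinates",
                n_comp, sizes[giant], n,
            )
            mask = comps == giant
        else:
            mask = np.ones(n, dtype=bool)

        Wg = W[mask][:, mask]
        m = int(mask.sum())
        deg = np.asarray(Wg.sum(axis=1)).ravel()
        deg = np.maximum(deg, 1e-300)
        d_isq = 1.0 / np.sqrt(deg)
        S = sp.diags(d_isq) @ Wg @ sp.diags(d_isq)  # symmetric conjugate of D^-1 W

        k_eig = min(self.n_components + 1, m - 1) if m > 2 else m
        if m <= max(2 * k_eig, 200):
            lam, vec = np.linalg.eigh(np.asarray(S.todense()))
            lam, vec = lam[::-1], vec[:, ::-1]
            lam, vec = lam[:k_eig], vec[:, :k_eig]
        else:
            lam, vec = sp.linalg.eigsh(S, k=k_eig, which="LA")
            order = np.argsort(lam)[::-1]
            lam, vec = lam[order], vec[:, order]

        # convert to right eigenvectors of M = D^-1 W; drop the stationary one
        psi = vec * d_isq[:, None]
        keep = ~np.isclose(lam, 1.0, atol=1e-9)
        if keep.all():  # numerically imperfect stationary vector: drop the top
            keep[0] = False
        lam, psi = lam[keep], psi[:, keep]
        lam = np.clip(lam, -1.0, 1.0 - 1e-12)

        # deterministic sign: largest-|entry| coordinate positive; unit norm
        psi = psi / np.linalg.norm(psi, axis=0, keepdims=True)
        flip = psi[np.abs(psi).argmax(axis=0), np.arange(psi.shape[1])] < 0
        psi[:, flip] *= -1

        coords = np.full((n, psi.shape[1]), np.nan)
        coords[mask] = psi
        self.embedding_ = coords
        self.eigenvalues_ = lam
        self.n_selected_ = (
            select_eigengap(lam, self.eigengap_window) if lam.size >= 3 else lam.size
        )
        return self

    def fit_transform(self, X, y=None):
        return self.fit(X).embedding_


def diffusion_map(g, n_components: int = 40, eigengap_window: int = 40) -> DiffusionResult:
    """Compute a diffusion map on a neighbor graph (or affinity matrix)."""
    est = DiffusionMapEmbedding(
        n_components=n_components, eigengap_window=eigengap_window
    ).fit(g)
    return DiffusionResult(est.embedding_, est.eigenvalues_, est.n_selected_)


def embed_diffusion(adata: AnnData, k: int = 30, n_components: int = 40) -> DiffusionResult:
    """Diffusion map over the PCA coordinates; stores obsm/uns entries."""
    if "X_pca" not in adata.obsm:
        raise ValueError("run pca_to_variance first")
    g = knn_graph(adata.obsm["X_pca"], k=k, mode="adaptive_gaussian")
    dr = diffusion_map(g, n_components=n_components)
    adata.obsm["X_diffusion"] = dr.coordinates
    adata.uns["eigenvalues"] = dr.eigenvalues
    adata.uns["n_selected_dcs"] = dr.n_selected
    adata.obsm["X_multiscale"] = dr.multiscale()
    return dr


def correlate_genes_dc(
    adata: AnnData, coordinates: np.ndarray, layer: str = "normalized", top_n: int = 100
):
    """Pearson correlation of every gene with every diffusion component.

    Returns (table, top) where ``table`` is a tidy frame of r, p and per-DC
    BH FDR, and ``top`` maps each DC to its ``top_n`` genes by |r| among those
    with p < 0.01.  Constant genes are recorded as missing and excluded.
    """
    from statsmodels.stats.multitest import multipletests

    X = adata.layers[layer]
    X = np.asarray(X.todense() if sp.issparse(X) else X, dtype=np.float64)
    n = X.shape[0]
    sd = X.std(axis=0)
    const = sd == 0
    Xz = (X - X.mean(axis=0)) / np.where(const, 1.0, sd)
    frames, top = [], {}
    for j in range(coordinates.shape[1]):
        dc = coordinates[:, j]
        ok = np.isfinite(dc)
        dcz = (dc[ok] - dc[ok].mean()) / max(dc[ok].std(), 1e-300)
        r = Xz[ok].T @ dcz / ok.sum()
        r = np.clip(r, -1, 1)
        r[const] = np.nan
        with np.errstate(divide="ignore", invalid="ignore"):
            t = r * np.sqrt((ok.sum() - 2) / (1 - r**2))
        p = 2 * stats.t.sf(np.abs(t), df=ok.sum() - 2)
        valid = ~const
        fdr = np.full(r.shape, np.nan)
        fdr[valid] = multipletests(p[valid], method="fdr_bh")[1]
        df = pd.DataFrame(
            {"gene": adata.var_names, "dc": f"DC{j}", "r": r, "p": p, "fdr": fdr}
        )
        frames.append(df)
        elig = df.dropna(subset=["r"]).query("p < 0.01")
        top[f"DC{j}"] = (
            elig.reindex(elig["r"].abs().sort_values(ascending=False).index)
            .head(top_n)["gene"]
            .tolist()
        )
    return pd.concat(frames, ignore_index=True), top


def temporal_axis_per_region(
    adata: AnnData,
    region: str,
    stage_order: tuple[str, ...],
    n_top_genes: int = 3000,
    target_variance: float = 0.75,
    k: int = 30,
    seed: int = 0,
):
    """Recompute geometry within one region; DC0 is the temporal axis.

    The subset is re-normalized (median changes with the cell set), re-embedded
    and a fresh diffusion map computed.  DC0 is oriented so its Spearman
    correlation with somite stage is positive; the correlation is returned as
    the validation statistic (NaN for single-stage data).
    """
    from .io import subset as subset_ds
    from .preprocess import normalize_log, pca_to_variance, select_hvg

    mask = (adata.obs["region"] == region).to_numpy()
    if mask.sum() < k + 1:
        raise ValueError(f"region {region!r} has too few cells")
    ds = subset_ds(adata, mask)
    normalize_log(ds)
    select_hvg(ds, n_top=min(n_top_genes, ds.n_vars))
    pca_to_variance(ds, target=target_variance, seed=seed)
    dr = embed_diffusion(ds, k=min(k, ds.n_obs - 1))

    stage_idx = pd.Categorical(
        ds.obs["stage_label"], categories=list(stage_order), ordered=True
    ).codes.astype(float)
    dc0 = dr.coordinates[:, 0]
    ok = np.isfinite(dc0)
    if len(np.unique(stage_idx[ok])) < 2:
        rho = np.nan
        logger.info("single-stage data: temporal validation not applicable")
    else:
        rho = stats.spearmanr(dc0[ok], stage_idx[ok]).statistic
        if rho < 0:
            dr.coordinates[:, 0] *= -1
            ds.obsm["X_diffusion"][:, 0] *= -1
            rho = -rho
    return ds, dr, float(rho)


def identify_axis_dcs(adata: AnnData, coordinates: np.ndarray, marker_sets: dict):
    """Map named axes to diffusion components via marker signature correlation.

    ``marker_sets`` maps an axis name (e.g. "ap", "ml") to a GeneSet whose
    score should vary along that axis.  Each axis is assigned the DC with the
    largest |Spearman| between the DC and the signature score; returns
    {axis: (dc_index, rho)}.  DC indices are labels of sorted eigenvalues;
    the axis↔DC mapping is always established from markers, never hard-coded.
    """
    from .classify import signature_score

    out = {}
    for axis, gs in marker_sets.items():
        score = signature_score(adata, gs)
        best, best_rho = 0, 0.0
        for j in range(coordinates.shape[1]):
            dc = coordinates[:, j]
            ok = np.isfinite(dc)
            rho = stats.spearmanr(dc[ok], score[ok]).statistic
            if np.abs(rho) > np.abs(best_rho):
                best, best_rho = j, rho
        out[axis] = (best, float(best_rho))
    return out
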