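"""Stage orchestration shared by the CLI and the acceptance script.

Each stage takes an AnnData dataset and a :class:`PipelineConfig`, mutates a
copy or returns new artifacts, and never mutates its input container file.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from anndata import AnnData

from .config import PipelineConfig
from .classify import assign_regions
from .diffusion import embed_diffusion, identify_axis_dcs, DiffusionResult
from .preprocess import normalize_log, pca_to_variance, regress_cell_cycle, select_hvg
from .qc import basic_filters, cluster_quality_filter, detect_library_modes
from .spatial import (
    cluster_trends,
    fit_trends,
    impute,
    local_autocorrelation,
    module_hierarchy,
    select_spatial_genes,
)

logger = logging.getLogger(__name__)


def run_qc(adata: AnnData, cfg: PipelineConfig):
    """Basic filters, KDE mode detection, cluster-level low-quality removal."""
    ds, basic_report = basic_filters(
        adata,
        min_umis=cfg.min_umis,
        max_mito=cfg.max_mito,
        complexity_resid=cfg.complexity_resid,
    )
    modes = detect_library_modes(ds)
    if modes.unimodal:
        logger.info("library-size distribution unimodal; no cluster filtering")
        ds.obs["quality_class"] = "high"
        return ds, basic_report, None, modes
    ds, cluster_report = cluster_quality_filter(
        ds, modes, k=cfg.qc_cluster_k, p_cutoff=cfg.z_cutoff, seed=cfg.seed
    )
    return ds, basic_report, cluster_report, modes


def embed_dataset(
    adata: AnnData, cfg: PipelineConfig, curated=(), cc_sets=None
) -> AnnData:
    """Normalize, select HVGs, optional cell-cycle regression, PCA."""
    normalize_log(adata)
    if cc_sets:
        regress_cell_cycle(adata, cc_sets)
    select_hvg(adata, n_top=min(cfg.n_top_genes, adata.n_vars), curated=tuple(curated))
    pca_to_variance(adata, target=cfg.pca_target, seed=cfg.seed)
    return adata


def compute_axes(adata: AnnData, cfg: PipelineConfig) -> DiffusionResult:
    """Diffusion map + eigengap selection + multiscale space on the dataset."""
    return embed_diffusion(adata, k=cfg.k_neighbors)


def spatial_gene_catalog(
    adata: AnnData,
    dr: DiffusionResult,
    cfg: PipelineConfig,
    ap_dc: int,
    ml_dc: int,
):
    """Autocorrelation selection on the three latent spaces.

    Returns ({space: result frame}, {space: selected genes}).  The spaces are
    the AP-matched DC alone, the ML-matched DC alone, and multiscale space on
    the eigengap-selected top components.
    """
    n_ms = max(dr.n_selected, ap_dc + 1, ml_dc + 1)  # span the identified axes
    spaces = {
        "dc_ap": dr.coordinates[:, ap_dc],
        "dc_ml": dr.coordinates[:, ml_dc],
        "multiscale": dr.multiscale(n_ms),
    }
    results, selections = {}, {}
    for name, latent in spaces.items():
        res = local_autocorrelation(adata, latent, k=cfg.k_neighbors)
        sel = select_spatial_genes(
            res,
            fdr_max=cfg.autocorr_fdr,
            z_min=cfg.autocorr_zmin,
            range_min=cfg.autocorr_range_min,
        )
        results[name], selections[name] = res, sel
    return results, selections


def axis_trends(
    adata: AnnData,
    axis: np.ndarray,
    genes,
    cfg: PipelineConfig,
    latent: np.ndarray | None = None,
):
    """Impute (if needed), fit per-gene trends along the axis, cluster them."""
    if "imputed" not in adata.layers:
        if latent is None:
            latent = adata.obsm["X_pca"]
        impute(adata, latent, k=cfg.impute_k, t=cfg.impute_t)
    ts = fit_trends(adata, axis, genes, n_bins=cfg.trend_bins)
    if len(genes) > cfg.trend_cluster_k:
        cluster_trends(ts, k=cfg.trend_cluster_k, seed=cfg.seed)
    return ts


def discover_modules(adata: AnnData, genes, cfg: PipelineConfig):
    return module_hierarchy(adata, genes, cut_distances=tuple(cfg.cut_distances))


def late_stage_mask(adata: AnnData) -> np.ndarray:
    """Cells from the two latest somite-stage bins (the developed neural plate)."""
    return adata.obs["stage_label"].isin(["7-9 somites", "10+ somites"]).to_numpy()
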