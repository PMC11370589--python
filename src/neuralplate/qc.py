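"""Quality-control filtering.

Three basic per-cell filters (library size, library complexity, mitochondrial
fraction) followed by a distribution-level step: a kernel-density fit to the
log10 library-size distribution detects a bimodal split into high- and
low-quality modes, and cells are then removed *per fine cluster* — each
community on a k=8 nearest-neighbor graph is kept or dropped wholesale by a
one-sided Z-test of its mean log10 library size against the high-quality mode.
Filtering by cluster rather than a hard threshold retains cells by phenotypic
similarity instead of a single cutoff.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import stats

from .io import subset

logger = logging.getLogger(__name__)


@dataclass
class LibraryModes:
    """Result of KDE mode detection on log10 library size."""

    n_modes: int
    mode_positions: np.ndarray  # log10 libsize at each density maximum, ascending
    boundary: float | None  # density minimum separating low/high (2 modes)
    labels: pd.Series | None  # "high"/"low" per cell when 2+ modes
    bandwidth: float
    grid: np.ndarray = field(repr=False, default=None)
    density: np.ndarray = field(repr=False, default=None)

    @property
    def unimodal(self) -> bool:
        return self.n_modes == 1


@dataclass
class QCReport:
    n_input: int
    n_removed_libsize: int = 0
    n_removed_complexity: int = 0
    n_removed_mito: int = 0
    n_removed_cluster_reassignment: int = 0
    removal_reason: pd.Series | None = None  # primary reason per removed cell
    quality_class: pd.Series | None = None
    mode_boundaries: tuple | None = None
    kde_bandwidth: float | None = None

    @property
    def n_removed(self) -> int:
        return (
            self.n_removed_libsize
            + self.n_removed_complexity
            + self.n_removed_mito
            + self.n_removed_cluster_reassignment
        )

    @property
    def n_kept(self) -> int:
        return self.n_input - self.n_removed

    def summary(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_kept": self.n_kept,
            "n_removed_libsize": self.n_removed_libsize,
            "n_removed_complexity": self.n_removed_complexity,
            "n_removed_mito": self.n_removed_mito,
            "n_removed_cluster_reassignment": self.n_removed_cluster_reassignment,
        }


def complexity_residuals(adata: AnnData) -> np.ndarray:
    """OLS residuals of log10(genes detected) on log10(library size)."""
    x = np.log10(adata.obs["total_umis"].to_numpy().astype(float))
    y = np.log10(adata.obs["n_genes_detected"].to_numpy().astype(float))
    X = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def basic_filters(
    adata: AnnData,
    min_umis: int = 1000,
    max_mito: float = 0.20,
    complexity_resid: float = 0.1,
) -> tuple[AnnData, QCReport]:
    """Apply the three per-cell filters.

    Keeps cells with library size > ``min_umis``, mitochondrial fraction
    < ``max_mito``, and complexity residual > ``-complexity_resid`` (cells
    whose gene count falls more than the cutoff below the log–log regression
    line have one predominant gene program and are removed).  The complexity
    regression is iterated to a fixed point — removing outliers and refitting
    until no further cell fails — so the filter is order-stable (applying it
    twice equals once).

    The primary removal reason is assigned in order libsize → complexity →
    mito, so each removed cell has exactly one reason.
    """
    if adata.n_obs < 10:
        raise ValueError("need at least 10 cells for the complexity regression")
    total = adata.obs["total_umis"].to_numpy()
    pct_mito = adata.obs["pct_mito"].to_numpy()
    fail_lib = total <= min_umis
    fail_mito = pct_mito >= max_mito

    # the regression is fit on cells passing the other filters, iterated to a
    # fixed point, so the surviving set reproduces itself on re-application
    x = np.log10(total.astype(float))
    y = np.log10(adata.obs["n_genes_detected"].to_numpy().astype(float))
    fail_cpx = np.zeros(adata.n_obs, dtype=bool)
    for _ in range(100):  # converges in a few rounds
        keep = ~(fail_cpx | fail_lib | fail_mito)
        X = np.column_stack([np.ones(keep.sum()), x[keep]])
        beta, *_ = np.linalg.lstsq(X, y[keep], rcond=None)
        resid = y - (beta[0] + beta[1] * x)
        new_fail = fail_cpx | (resid < -complexity_resid)
        if (new_fail == fail_cpx).all():
            break
        fail_cpx = new_fail

    reason = pd.Series("", index=adata.obs_names, dtype=object)
    reason[fail_mito] = "mito"
    reason[fail_cpx] = "complexity"
    reason[fail_lib] = "libsize"  # highest precedence last

    keep = ~(fail_lib | fail_cpx | fail_mito)
    report = QCReport(
        n_input=adata.n_obs,
        n_removed_libsize=int((reason == "libsize").sum()),
        n_removed_complexity=int((reason == "complexity").sum()),
        n_removed_mito=int((reason == "mito").sum()),
        removal_reason=reason[~keep],
    )
    if not keep.any():
        raise ValueError("all cells removed by basic filters")
    return subset(adata, keep.to_numpy() if hasattr(keep, "to_numpy") else keep), report


def _basin_masses(x: np.ndarray, grid: np.ndarray, dens: np.ndarray, peaks: list):
    """Fraction of cells in each peak's basin (split at density minima)."""
    bounds = [grid[p0 + int(np.argmin(dens[p0 : p1 + 1]))] for p0, p1 in zip(peaks, peaks[1:])]
    edges = [-np.inf, *bounds, np.inf]
    return np.array(
        [np.mean((x >= lo) & (x < hi)) for lo, hi in zip(edges, edges[1:])]
    ), bounds


def detect_library_modes(
    adata: AnnData,
    grid_size: int = 512,
    min_mode_mass: float = 0.02,
    max_saddle_ratio: float = 0.95,
) -> LibraryModes:
    """Gaussian-KDE mode detection on log10 library size (Scott bandwidth).

    Modes are local maxima of the density on a ``grid_size``-point grid that
    are (i) separated by a genuine valley — the saddle density between two
    adjacent maxima must fall below ``max_saddle_ratio`` of the smaller
    maximum, otherwise the smaller is merged away as a sampling wiggle — and
    (ii) substantial — each mode's basin must hold at least ``min_mode_mass``
    of the cells.  With exactly two modes cells are assigned high/low by the
    density-minimum boundary between them; with more, the top two maxima by
    density are used (warning logged); one maximum yields the unimodal flag.
    """
    if adata.n_obs < 100:
        raise ValueError("need at least 100 cells for KDE mode detection")
    from scipy.signal import find_peaks

    x = np.log10(adata.obs["total_umis"].to_numpy().astype(float))
    kde = stats.gaussian_kde(x, bw_method="scott")
    pad = 0.05 * (x.max() - x.min() + 1e-12)
    grid = np.linspace(x.min() - pad, x.max() + pad, grid_size)
    dens = kde(grid)
    peaks = list(find_peaks(dens)[0])

    # merge peaks lacking a real valley between them (shoulder wiggles)
    merged = True
    while merged and len(peaks) > 1:
        merged = False
        for a, b in zip(peaks, peaks[1:]):
            saddle = dens[a : b + 1].min()
            if saddle > max_saddle_ratio * min(dens[a], dens[b]):
                peaks.remove(a if dens[a] < dens[b] else b)
                merged = True
                break
    while len(peaks) > 1:
        masses, _ = _basin_masses(x, grid, dens, peaks)
        weakest = int(np.argmin(masses))
        if masses[weakest] >= min_mode_mass:
            break
        peaks.pop(weakest)
    n_modes = len(peaks)

    if n_modes <= 1:
        pos = grid[peaks] if peaks else np.array([grid[np.argmax(dens)]])
        return LibraryModes(1, pos, None, None, kde.factor, grid, dens)
    if n_modes > 2:
        logger.warning("found %d density modes; using top 2 by density", n_modes)
        top2 = sorted(sorted(peaks, key=lambda p: -dens[p])[:2])
    else:
        top2 = peaks
    lo_idx, hi_idx = top2
    boundary = grid[lo_idx + int(np.argmin(dens[lo_idx : hi_idx + 1]))]
    high_mass = float(np.mean(x >= boundary))
    if high_mass < 0.25:
        # the upper "mode" is a minority tail bump, not the main high-quality
        # population; treating it as the reference would purge everything
        logger.info(
            "upper density mode holds only %.0f%% of cells; treating the "
            "distribution as unimodal", 100 * high_mass,
        )
        return LibraryModes(
            1, np.array([grid[int(np.argmax(dens))]]), None, None, kde.factor, grid, dens
        )
    labels = pd.Series(
        np.where(x >= boundary, "high", "low"), index=adata.obs_names, name="library_mode"
    )
    return LibraryModes(
        2, grid[[lo_idx, hi_idx]], float(boundary), labels, kde.factor, grid, dens
    )


def cluster_quality_filter(
    adata: AnnData,
    modes: LibraryModes,
    k: int = 8,
    p_cutoff: float = 1e-10,
    seed: int = 0,
) -> tuple[AnnData, QCReport]:
    """Remove whole fine clusters belonging to the low library-size mode.

    Cells are finely clustered by graph community detection on a k=8
    nearest-neighbor graph over PCA coordinates; for each cluster a one-sided
    two-sample Z-test compares the cluster's mean log10 library size with the
    high-quality mode's distribution, and clusters with p < ``p_cutoff`` on the
    low side are removed wholesale.  Per-cell mode labels are replaced by
    cluster-level labels.  Mean gene count per cluster is logged as a secondary
    diagnostic.
    """
    if modes.labels is None:
        raise ValueError("detect_library_modes did not find two modes")
    from .preprocess import log_normalize, pca_to_variance, select_hvg, knn_graph
    from .classify import graph_cluster

    ds = adata.copy()
    log_normalize(ds)
    hvg = select_hvg(ds, n_top=min(3000, ds.n_vars))
    pca = pca_to_variance(ds, hvg_mask=hvg.selected.to_numpy(), seed=seed)
    g = knn_graph(pca, k=k, mode="unit")
    clusters = graph_cluster(g, seed=seed)

    x = np.log10(ds.obs["total_umis"].to_numpy().astype(float))
    high = modes.labels.to_numpy() == "high"
    mu_h, sd_h, n_h = x[high].mean(), x[high].std(ddof=1), int(high.sum())

    quality = pd.Series("high", index=ds.obs_names, dtype=object)
    removed = np.zeros(ds.n_obs, dtype=bool)
    for c in np.unique(clusters):
        members = clusters == c
        xc = x[members]
        n_c = int(members.sum())
        se = np.sqrt(sd_h**2 / n_h + (xc.std(ddof=1) ** 2 if n_c > 1 else 0.0) / n_c)
        z = (xc.mean() - mu_h) / se if se > 0 else 0.0
        p_low = stats.norm.cdf(z)
        logger.debug(
            "cluster %d: n=%d mean_log10_libsize=%.3f mean_genes=%.0f p_low=%.2e",
            c, n_c, xc.mean(),
            ds.obs["n_genes_detected"].to_numpy()[members].mean(), p_low,
        )
        if p_low < p_cutoff:
            removed[members] = True
            quality.iloc[np.flatnonzero(members)] = "low"

    reason = pd.Series("cluster_low_quality", index=ds.obs_names[removed], dtype=object)
    report = QCReport(
        n_input=ds.n_obs,
        n_removed_cluster_reassignment=int(removed.sum()),
        removal_reason=reason,
        quality_class=quality,
        mode_boundaries=(modes.boundary,),
        kde_bandwidth=modes.bandwidth,
    )
    if removed.all():
        raise ValueError("cluster quality filter removed every cell")
    out = subset(adata, ~removed)
    out.obs["quality_class"] = "high"
    return out, report
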