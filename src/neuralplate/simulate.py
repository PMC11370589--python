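"""Ground-truthed synthetic cranial-neural-plate tissue generator.

Emulates a staged droplet scRNA-seq atlas of the cranial neural plate so that every
downstream stage (QC, axis reconstruction, spatially patterned gene selection,
module discovery, perturbation DE) can be scored against a known truth:

* each cell carries latent anterior–posterior (AP), mediolateral (ML) and
  temporal coordinates on [0, 1];
* regions derive from fixed AP/ML breakpoints (AP < 0.33 forebrain,
  < 0.66 midbrain/r1, else hindbrain; ML < 0.08 midline);
* patterned genes follow smooth templates over (ap, ml, time): logistic fronts
  along AP at the region breakpoints, monotone gradients or Gaussian bumps
  along ML, monotone ramps along time; null genes have constant rate;
* counts are negative binomial (Gamma–Poisson) with per-cell log-normal
  library size; a configurable fraction of low-quality cells has shrunken
  libraries, boosted mitochondrial load, and expression collapsed toward the
  50 highest-abundance genes (one predominant gene program);
* a treatment condition expands the "medial" ML program (ML templates peaking
  at the midline) and suppresses the lateral program, mimicking pharmacological
  activation of Hedgehog signalling.

Ground truth is returned as a :class:`TissueModel` sidecar, never written into
the ``obs`` fields the pipeline reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData

from .io import GeneSet, compute_cell_metrics

STAGE_LABELS = (
    "0 somites",
    "1-2 somites",
    "3 somites",
    "4-6 somites",
    "7-9 somites",
    "10+ somites",
)
AP_BREAKS = (0.33, 0.66)
ML_MIDLINE = 0.08
REGIONS = ("forebrain", "midbrain_r1", "hindbrain", "midline")


class SimConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SimConfig:
    """Reference conditions for the synthetic tissue.

    Defaults describe a down-scaled but structurally faithful sample:
    2,000 cells x 500 genes, six somite-stage bins with two replicates each,
    ~8-fold dynamic range for patterned genes (developmental markers are
    near on/off), droplet-typical NB dispersion 0.3 and log-normal library
    sizes with median ~5,000 UMIs.
    """

    seed: int = 0
    n_cells: int = 2000
    n_genes: int = 500
    n_ap: int = 60
    n_ml: int = 40
    n_both: int = 20
    n_time: int = 30
    n_markers_per_region: int = 6
    n_mito: int = 5
    n_ribo: int = 5
    n_stress: int = 10
    pattern_fold: float = 8.0
    marker_fold: float = 8.0
    nb_dispersion: float = 0.3
    libsize_log_mean: float = float(np.log(5000.0))
    libsize_log_sigma: float = 0.35
    low_quality_fraction: float = 0.0
    # low-quality cells keep "low to moderate" libraries: mostly above the
    # hard UMI cutoff, forming the second KDE mode the cluster filter removes
    low_quality_libsize_factor: float = 0.25
    # stressed leaky cells: ribosomal/stress program strongly up, moderate
    # mitochondrial elevation (below the hard 20% cutoff), and a mild bias
    # toward the highest-abundance genes; they pass the per-cell filters and
    # are removed by the KDE + cluster stage
    low_quality_mito_boost: float = 2.0
    # the stress program dominates the library in leaky/dying cells (~30% of
    # reads), which is what makes them cluster by quality rather than position
    low_quality_stress_boost: float = 20.0
    low_quality_collapse: float = 0.25
    nonneural_fraction: float = 0.0
    n_stages: int = 6
    n_replicates_per_stage: int = 2
    treatment_flag: bool = False
    treatment_effect: float = 2.0
    treatment_regions: tuple[str, ...] = ("forebrain", "midbrain_r1", "hindbrain")

    def __post_init__(self) -> None:
        n_markers = self.n_markers_per_region * len(REGIONS)
        n_special = (
            self.n_ap + self.n_ml + self.n_both + self.n_time
            + n_markers + self.n_mito + self.n_ribo + self.n_stress
        )
        if self.nonneural_fraction > 0:
            n_special += self.n_markers_per_region
        if n_special > self.n_genes:
            raise SimConfigError(
                f"gene-category counts ({n_special}) exceed n_genes ({self.n_genes})"
            )
        for name in ("low_quality_fraction", "nonneural_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise SimConfigError(f"{name} must be in [0, 1], got {v}")
        if not 1 <= self.n_stages <= len(STAGE_LABELS):
            raise SimConfigError("n_stages must be between 1 and 6")


@dataclass
class TissueModel:
    """Ground truth exported alongside a simulated dataset."""

    cells: pd.DataFrame
    genes: pd.DataFrame
    region_gene_sets: list[GeneSet]
    config: SimConfig
    treatment_truth: pd.DataFrame | None = None

    @property
    def patterned_genes(self) -> pd.Index:
        mask = self.genes["category"].isin(["ap", "ml", "both"])
        return self.genes.index[mask]


def _logistic(x: np.ndarray, center: float, sharpness: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-(x - center) / sharpness))


def _assign_regions(ap: np.ndarray, ml: np.ndarray) -> np.ndarray:
    region = np.where(
        ap < AP_BREAKS[0], "forebrain", np.where(ap < AP_BREAKS[1], "midbrain_r1", "hindbrain")
    ).astype(object)
    region[ml < ML_MIDLINE] = "midline"
    return region.astype(str)


def _build_gene_table(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """One row per gene: name, category, template parameters."""
    rows = []

    def add(name, category, **kw):
        row = {
            "gene_id": name,
            "category": category,
            "center": np.nan,
            "sharpness": np.nan,
            "direction": 0,
            "bump_width": np.nan,
            "medial": False,
            "lateral": False,
            "marker_region": "",
        }
        row.update(kw)
        rows.append(row)

    for i in range(cfg.n_mito):
        add(f"mt-sim{i + 1}", "mito")
    for i in range(cfg.n_ribo):
        add(f"Rps-sim{i + 1}", "ribo")
    for i in range(cfg.n_stress):
        add(f"stress_{i + 1}", "stress")  # GM42418-like cell-stress transcripts
    for region in REGIONS:
        for i in range(cfg.n_markers_per_region):
            add(f"mk_{region}_{i + 1}", "marker", marker_region=region)
    if cfg.nonneural_fraction > 0:
        for i in range(cfg.n_markers_per_region):
            add(f"mk_nonneural_{i + 1}", "marker", marker_region="nonneural")
    for i in range(cfg.n_ap):
        center = rng.choice(AP_BREAKS) + rng.normal(0, 0.04)
        add(
            f"ap_{i + 1:03d}", "ap",
            center=float(np.clip(center, 0.1, 0.9)),
            sharpness=float(rng.uniform(0.03, 0.08)),
            direction=int(rng.choice([-1, 1])),
        )
    for i in range(cfg.n_ml):
        if i % 2 == 0:  # monotone gradient; even = medial-high, odd = lateral-high
            direction = -1 if (i // 2) % 2 == 0 else 1
            add(
                f"ml_{i + 1:03d}", "ml",
                direction=direction,
                medial=direction < 0,
                lateral=direction > 0,
            )
        else:  # Gaussian bump
            center = float(rng.uniform(0.0, 0.9))
            add(
                f"ml_{i + 1:03d}", "ml",
                center=center,
                bump_width=float(rng.uniform(0.08, 0.2)),
                medial=center < 0.2,
                lateral=center > 0.7,
            )
    for i in range(cfg.n_both):
        add(
            f"both_{i + 1:03d}", "both",
            center=float(np.clip(rng.choice(AP_BREAKS) + rng.normal(0, 0.04), 0.1, 0.9)),
            sharpness=float(rng.uniform(0.03, 0.08)),
            direction=int(rng.choice([-1, 1])),
        )
    for i in range(cfg.n_time):
        add(f"time_{i + 1:03d}", "time", direction=int(rng.choice([-1, 1])))
    n_null = cfg.n_genes - len(rows)
    for i in range(n_null):
        add(f"null_{i + 1:03d}", "null")

    genes = pd.DataFrame(rows).set_index("gene_id")
    genes["base_rate"] = np.exp(rng.normal(0.0, 1.0, size=len(genes)))
    # mito genes carry a realistic share of the library (~5% total)
    genes.loc[genes["category"] == "mito", "base_rate"] = (
        0.01 * genes["base_rate"].sum()
    )
    return genes


def _templates(
    genes: pd.DataFrame, ap: np.ndarray, ml: np.ndarray, tc: np.ndarray,
    region: np.ndarray, celltype: np.ndarray,
) -> np.ndarray:
    """cells × genes template matrix in [0, 1]."""
    n_cells = ap.shape[0]
    T = np.full((n_cells, len(genes)), 0.5)
    neural = celltype == "neural"
    for j, (g, row) in enumerate(genes.iterrows()):
        cat = row["category"]
        if cat in ("null", "ribo", "stress"):
            T[:, j] = 0.5
        elif cat == "mito":
            T[:, j] = 0.5
        elif cat == "marker":
            if row["marker_region"] == "nonneural":
                on = celltype == "nonneural"
            else:
                on = neural & (region == row["marker_region"])
            T[:, j] = np.where(on, 1.0, 0.05)
        elif cat == "ap":
            t = _logistic(ap, row["center"], row["sharpness"])
            T[neural, j] = (t if row["direction"] > 0 else 1 - t)[neural]
        elif cat == "ml":
            if np.isfinite(row["bump_width"]):
                t = np.exp(-0.5 * ((ml - row["center"]) / row["bump_width"]) ** 2)
            else:
                t = ml if row["direction"] > 0 else 1 - ml
            if row["medial"]:
                # the floor-plate program saturates in the ventral midline:
                # medial genes are maximally induced there, making the
                # midline a discrete identity, not just the end of a gradient
                t = np.where(region == "midline", 1.0, t)
            T[neural, j] = t[neural]
        elif cat == "both":
            t_ap = _logistic(ap, row["center"], row["sharpness"])
            if row["direction"] < 0:
                t_ap = 1 - t_ap
            t_ml = 1 - ml  # medial-weighted AP fronts
            T[neural, j] = (t_ap * t_ml)[neural]
        elif cat == "time":
            T[:, j] = tc if row["direction"] > 0 else 1 - tc
        else:  # pragma: no cover
            raise AssertionError(cat)
    return T


def expected_rates(
    cfg: SimConfig, genes: pd.DataFrame, templates: np.ndarray
) -> np.ndarray:
    """Per-cell relative expression rates (rows sum to 1) before sampling."""
    fold = np.where(
        genes["category"].isin(["ap", "ml", "both", "time"]), cfg.pattern_fold,
        np.where(genes["category"] == "marker", cfg.marker_fold, 1.0),
    )
    rates = genes["base_rate"].to_numpy() * fold[None, :] ** (templates - 0.5)
    return rates / rates.sum(axis=1, keepdims=True)


def _nb_sample(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """Gamma–Poisson draw with Var = m + dispersion * m^2."""
    if dispersion <= 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def _simulate_counts(
    cfg: SimConfig, rng: np.random.Generator, genes: pd.DataFrame,
    rel_rates: np.ndarray, libsize: np.ndarray, low_quality: np.ndarray,
) -> sp.csr_matrix:
    p = rel_rates.copy()
    if low_quality.any():
        is_mito = genes["category"].isin(["mito", "ribo"]).to_numpy()
        is_stress = (genes["category"] == "stress").to_numpy()
        p[np.ix_(low_quality, is_mito)] *= cfg.low_quality_mito_boost
        p[np.ix_(low_quality, is_stress)] *= cfg.low_quality_stress_boost
        p /= p.sum(axis=1, keepdims=True)
        # collapse toward the 50 highest-abundance genes: one predominant program
        top = np.argsort(genes["base_rate"].to_numpy())[::-1][:50]
        p_top = np.zeros_like(p[low_quality])
        p_top[:, top] = p[low_quality][:, top]
        p_top /= p_top.sum(axis=1, keepdims=True)
        a = cfg.low_quality_collapse
        p[low_quality] = a * p_top + (1 - a) * p[low_quality]
    mean = libsize[:, None] * p
    counts = _nb_sample(rng, mean, cfg.nb_dispersion)
    return sp.csr_matrix(counts.astype(np.int64))


def _simulate(cfg: SimConfig, *, treated: bool = False):
    rng = np.random.default_rng(cfg.seed)
    genes = _build_gene_table(cfg, rng)

    n = cfg.n_cells
    ap = rng.uniform(0, 1, n)
    ml = rng.uniform(0, 1, n)
    stage = rng.integers(0, cfg.n_stages, n)
    tc = stage / max(cfg.n_stages - 1, 1)
    rep = rng.integers(0, cfg.n_replicates_per_stage, n)
    region = _assign_regions(ap, ml)
    celltype = np.full(n, "neural", dtype=object)
    if cfg.nonneural_fraction > 0:
        n_nn = int(round(cfg.nonneural_fraction * n))
        celltype[rng.choice(n, n_nn, replace=False)] = "nonneural"
    region = np.where(celltype == "neural", region, "unset")

    n_low = int(round(cfg.low_quality_fraction * n))
    low_quality = np.zeros(n, dtype=bool)
    if n_low:
        low_quality[rng.choice(n, n_low, replace=False)] = True

    T = _templates(genes, ap, ml, tc, region, celltype)
    rel = expected_rates(cfg, genes, T)
    if treated:
        eff = cfg.treatment_effect
        affected = np.isin(region, cfg.treatment_regions)
        medial = (genes["medial"] | (genes["marker_region"] == "midline")).to_numpy()
        lateral = genes["lateral"].to_numpy()
        rel = rel.copy()
        rel[np.ix_(affected, medial)] *= eff
        rel[np.ix_(affected, lateral)] /= eff
        rel /= rel.sum(axis=1, keepdims=True)

    libsize = rng.lognormal(cfg.libsize_log_mean, cfg.libsize_log_sigma, n)
    libsize[low_quality] *= cfg.low_quality_libsize_factor
    counts = _simulate_counts(cfg, rng, genes, rel, libsize, low_quality)

    obs = pd.DataFrame(
        {
            "replicate_id": [f"s{s}_r{r}" for s, r in zip(stage, rep)],
            "stage_label": [STAGE_LABELS[s] for s in stage],
            "treatment": "treated" if treated else "control",
        },
        index=pd.Index([f"cell_{i:05d}" for i in range(n)], name="cell_id"),
    )
    adata = AnnData(X=counts, obs=obs, var=pd.DataFrame(index=genes.index.copy()))
    adata.layers["counts"] = adata.X
    compute_cell_metrics(adata)

    cells = pd.DataFrame(
        {
            "ap_coord": ap,
            "ml_coord": ml,
            "time_coord": tc,
            "stage": stage,
            "region": region,
            "cell_type": celltype,
            "low_quality": low_quality,
        },
        index=adata.obs_names.copy(),
    )
    region_sets = [
        GeneSet(r, tuple(genes.index[genes["marker_region"] == r])) for r in REGIONS
    ]
    model = TissueModel(cells=cells, genes=genes, region_gene_sets=region_sets, config=cfg)
    return adata, model


def simulate_tissue(cfg: SimConfig) -> tuple[AnnData, TissueModel]:
    """Simulate one condition. Fixed seed ⇒ bit-reproducible counts."""
    return _simulate(cfg, treated=False)


def simulate_treatment_pair(cfg: SimConfig) -> tuple[AnnData, AnnData, TissueModel]:
    """Simulate a control/treated pair sharing one ground-truth tissue model.

    The treated dataset multiplies medial-program gene rates by
    ``treatment_effect`` and divides lateral-program rates by it within
    ``treatment_regions``; the returned truth table lists per-region log2
    fold changes for every perturbed gene.
    """
    if cfg.treatment_effect < 1.0:
        raise SimConfigError("treatment_effect must be >= 1")
    control, model = _simulate(replace(cfg, treatment_flag=False), treated=False)
    treated, _ = _simulate(replace(cfg, treatment_flag=True), treated=True)

    genes = model.genes
    medial = (genes["medial"] | (genes["marker_region"] == "midline")).to_numpy()
    lateral = genes["lateral"].to_numpy()
    lfc = np.log2(cfg.treatment_effect)
    rows = []
    for region in cfg.treatment_regions:
        for g, m, l in zip(genes.index, medial, lateral):
            if m or l:
                rows.append({"gene_id": g, "region": region, "log2fc": lfc if m else -lfc})
    model.treatment_truth = pd.DataFrame(rows)
    return control, treated, model


def simulate_null_matrix(n_cells: int, n_genes: int, seed: int = 0) -> AnnData:
    """I.i.d. negative-binomial counts with no structure (type-I-error oracle).

    Each gene has a constant expected rate across cells; there is no library
    size variation, spatial template, or cell substructure.
    """
    if n_cells < 2:
        raise SimConfigError("need at least 2 cells (graph stages need >= k+1)")
    rng = np.random.default_rng(seed)
    means = np.exp(rng.normal(0.0, 1.0, n_genes))
    counts = _nb_sample(rng, np.tile(means, (n_cells, 1)), 0.3)
    adata = AnnData(
        X=sp.csr_matrix(counts.astype(np.int64)),
        obs=pd.DataFrame(index=pd.Index([f"cell_{i:05d}" for i in range(n_cells)])),
        var=pd.DataFrame(index=pd.Index([f"null_{j:04d}" for j in range(n_genes)])),
    )
    adata.layers["counts"] = adata.X
    compute_cell_metrics(adata)
    return adata
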