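"""Pipeline configuration.

Every stage parameter carries a fixed, documented default
(the frozen `paper_defaults` profile): library-size filter > 1,000 UMIs, mitochondrial fraction
< 0.20, complexity residual cutoff 0.1, fine clustering k = 8 with a 1e-10
Z-test cutoff, 3,000 highly variable genes, PCA to 75% variance, k = 30
nearest neighbors, eigengap searched in the first 40 eigenvalues, MAGIC-style
imputation with k = 5 / t = 3, 500 trend bins, trend clustering k = 20,
autocorrelation FDR < 1e-5 with Z >= 10, Ward cut distances 10/6/4, hurdle DE
FDR < 0.001 with |effect| > 0.24 and 0.10 for cross-region propagation.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    seed: int = 0

    # qc
    min_umis: int = 1000
    max_mito: float = 0.20
    complexity_resid: float = 0.1
    qc_cluster_k: int = 8
    z_cutoff: float = 1e-10

    # embedding
    n_top_genes: int = 3000
    pca_target: float = 0.75
    k_neighbors: int = 30
    curated_markers_file: str | None = None
    cc_gene_sets_file: str | None = None

    # diffusion
    eigengap_window: int = 40

    # spatial genes
    impute_k: int = 5
    impute_t: int = 3
    trend_bins: int = 500
    trend_cluster_k: int = 20
    autocorr_fdr: float = 1e-5
    autocorr_zmin: float | str = 10.0
    autocorr_range_min: float = 1.0
    cut_distances: list = field(default_factory=lambda: [10.0, 6.0, 4.0])

    # differential expression
    de_fdr: float = 0.001
    de_effect: float = 0.24
    de_propagate_effect: float = 0.10
    de_regions: list = field(
        default_factory=lambda: ["forebrain", "midbrain_r1", "hindbrain"]
    )

    def __post_init__(self) -> None:
        for name in (
            "min_umis", "max_mito", "complexity_resid", "qc_cluster_k", "z_cutoff",
            "n_top_genes", "pca_target", "k_neighbors", "eigengap_window",
            "impute_k", "impute_t", "trend_bins", "trend_cluster_k",
            "autocorr_fdr", "de_fdr", "de_effect", "de_propagate_effect",
        ):
            v = getattr(self, name)
            if not isinstance(v, (int, float)) or v <= 0:
                raise ConfigError(f"{name} must be a positive number, got {v!r}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise ConfigError(f"unknown config keys: {unknown}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)


def paper_defaults() -> PipelineConfig:
    """The frozen profile reproducing every published parameter."""
    return PipelineConfig()
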