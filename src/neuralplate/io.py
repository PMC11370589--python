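"""Data model and file I/O.

The pipeline's dataset container is :class:`anndata.AnnData`:

* ``X`` / ``layers["counts"]`` — cells × genes UMI counts (sparse CSR, integer).
* ``layers["normalized"]`` — ln(1 + median-normalized counts).
* ``layers["imputed"]`` — graph-diffusion smoothed expression (display/trends only).
* ``obs`` — per-cell metadata (replicate_id, stage_label, total_umis,
  n_genes_detected, pct_mito, pct_ribo, quality_class, cluster_id, cell_type,
  region, treatment).
* ``var`` — per-gene metadata (n_cells_expressing, is_mito, is_ribo,
  is_curated_marker).
* ``obsm`` + ``uns["eigenvalues"]`` — embeddings (X_pca, X_diffusion,
  X_multiscale) with per-component eigenvalues for diffusion maps.
* ``obsp`` — cell × cell neighbor graphs.

On disk the 10x convention is genes × cells (matrix.mtx + barcodes.tsv +
features.tsv); matrices are transposed to cells × genes on load.  Subsetting
drops embeddings and graphs: geometry must be recomputed on subsets.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData
from scipy.io import mmread

logger = logging.getLogger(__name__)

MITO_PREFIXES = ("mt-",)
RIBO_PREFIXES = ("Rps", "Rpl")

OBS_DEFAULTS = {
    "replicate_id": "unset",
    "stage_label": "unset",
    "quality_class": "unset",
    "cell_type": "unset",
    "region": "unset",
    "treatment": "unset",
}


class DataLoadError(ValueError):
    """Structured error for malformed or inconsistent on-disk inputs."""


class GeneSetError(ValueError):
    """Raised for malformed gene-set definition files."""


@dataclass(frozen=True)
class GeneSet:
    """A named signature with positive and optional negative marker genes."""

    name: str
    positive_genes: tuple[str, ...]
    negative_genes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.positive_genes:
            raise GeneSetError(f"gene set {self.name!r}: empty positive list")
        overlap = set(self.positive_genes) & set(self.negative_genes)
        if overlap:
            raise GeneSetError(
                f"gene set {self.name!r}: genes in both lists: {sorted(overlap)}"
            )

    def restrict(self, gene_ids) -> "GeneSet":
        """Drop genes absent from ``gene_ids`` (warns, never errors at parse time)."""
        present = set(gene_ids)
        pos = tuple(g for g in self.positive_genes if g in present)
        neg = tuple(g for g in self.negative_genes if g in present)
        dropped = (set(self.positive_genes) | set(self.negative_genes)) - present
        if dropped:
            logger.warning(
                "gene set %s: dropping %d genes absent from dataset",
                self.name,
                len(dropped),
            )
        if not pos:
            raise GeneSetError(
                f"gene set {self.name!r}: no positive genes present in dataset"
            )
        return GeneSet(self.name, pos, neg)


def _is_prefixed(names: pd.Index, prefixes, *, case_insensitive: bool) -> np.ndarray:
    out = np.zeros(len(names), dtype=bool)
    for p in prefixes:
        if case_insensitive:
            hit = names.str.lower().str.startswith(p.lower())
        else:
            hit = names.str.startswith(p)
        out |= np.asarray(hit)
    return out


def compute_cell_metrics(adata: AnnData) -> None:
    """(Re)compute per-cell and per-gene QC metrics from the count matrix.

    Derived statistics always equal direct recomputation from counts.
    """
    counts = sp.csr_matrix(adata.layers["counts"])
    total = np.asarray(counts.sum(axis=1)).ravel()
    adata.obs["total_umis"] = total.astype(np.int64)
    adata.obs["n_genes_detected"] = np.asarray((counts > 0).sum(axis=1)).ravel()

    names = adata.var_names
    is_mito = _is_prefixed(names, MITO_PREFIXES, case_insensitive=True)
    is_ribo = _is_prefixed(names, RIBO_PREFIXES, case_insensitive=False)
    adata.var["is_mito"] = is_mito
    adata.var["is_ribo"] = is_ribo
    adata.var["n_cells_expressing"] = np.asarray((counts > 0).sum(axis=0)).ravel()

    with np.errstate(invalid="ignore", divide="ignore"):
        mito = np.asarray(counts[:, is_mito].sum(axis=1)).ravel()
        ribo = np.asarray(counts[:, is_ribo].sum(axis=1)).ravel()
        safe = np.maximum(total, 1)
        adata.obs["pct_mito"] = mito / safe
        adata.obs["pct_ribo"] = ribo / safe
    for col, default in OBS_DEFAULTS.items():
        if col not in adata.obs:
            adata.obs[col] = default


def load_mtx(dir_path) -> AnnData:
    """Load a 10x-style MatrixMarket triplet into an AnnData dataset.

    Expects ``matrix.mtx`` (genes × cells), ``barcodes.tsv`` (one cell id per
    line) and ``features.tsv`` (one gene id per line, first column used).
    """
    d = Path(dir_path)
    mtx = d / "matrix.mtx"
    barcodes = d / "barcodes.tsv"
    features = d / "features.tsv"
    for f in (mtx, barcodes, features):
        if not f.exists():
            raise DataLoadError(f"missing required file: {f}")
    m = mmread(str(mtx))
    cell_ids = pd.read_csv(barcodes, sep="\t", header=None)[0].astype(str)
    gene_ids = pd.read_csv(features, sep="\t", header=None)[0].astype(str)
    if m.shape != (len(gene_ids), len(cell_ids)):
        raise DataLoadError(
            f"matrix is {m.shape} but sidecars describe "
            f"{len(gene_ids)} genes × {len(cell_ids)} cells"
        )
    data = m.tocsr().data
    if data.size and (np.any(data < 0) or np.any(data != np.round(data))):
        raise DataLoadError("count matrix has negative or non-integer entries")
    if cell_ids.duplicated().any() or gene_ids.duplicated().any():
        raise DataLoadError("duplicate cell or gene identifiers")
    counts = sp.csr_matrix(m.T).astype(np.int64)
    adata = AnnData(
        X=counts,
        obs=pd.DataFrame(index=pd.Index(cell_ids, name="cell_id")),
        var=pd.DataFrame(index=pd.Index(gene_ids, name="gene_id")),
    )
    adata.layers["counts"] = adata.X
    compute_cell_metrics(adata)
    return adata


def save_dataset(adata: AnnData, path) -> None:
    """Write the dataset to a single hierarchical HDF5 container (.h5ad)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        adata.write_h5ad(Path(path))


def load_dataset(path) -> AnnData:
    """Load a dataset written by :func:`save_dataset`.

    Corrupt or truncated containers raise :class:`DataLoadError` rather than
    returning a silently partial dataset.
    """
    import anndata

    p = Path(path)
    if not p.exists():
        raise DataLoadError(f"no such file: {p}")
    try:
        return anndata.read_h5ad(p)
    except Exception as exc:  # h5py raises OSError on truncation
        raise DataLoadError(f"could not read dataset container {p}: {exc}") from exc


def load_gene_sets(path) -> list[GeneSet]:
    """Parse a tab-delimited gene-set file.

    One set per row: ``name<TAB>pos1,pos2,...[<TAB>neg1,neg2,...]``.
    Duplicate set names or empty positive lists are parse errors; genes absent
    from a particular dataset are dropped later, at use time.
    """
    sets: list[GeneSet] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise GeneSetError(f"line {lineno}: expected at least 2 columns")
            name = parts[0].strip()
            if name in seen:
                raise GeneSetError(f"line {lineno}: duplicate set name {name!r}")
            seen.add(name)
            pos = tuple(g.strip() for g in parts[1].split(",") if g.strip())
            neg = ()
            if len(parts) > 2 and parts[2].strip():
                neg = tuple(g.strip() for g in parts[2].split(",") if g.strip())
            if not pos:
                raise GeneSetError(f"line {lineno}: set {name!r} has no positive genes")
            sets.append(GeneSet(name, pos, neg))
    return sets


def save_gene_sets(sets: list[GeneSet], path) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            fh.write(
                f"{gs.name}\t{','.join(gs.positive_genes)}\t"
                f"{','.join(gs.negative_genes)}\n"
            )


def subset(adata: AnnData, cell_mask=None, gene_mask=None) -> AnnData:
    """Subset cells and/or genes, dropping embeddings and graphs.

    Geometry (PCA, diffusion maps, kNN graphs) is sample-set dependent and the
    analysis recomputes it per region/stage subset, so stale embeddings are
    removed rather than sliced.  Per-gene/per-cell derived metrics are
    recomputed on the subset.
    """
    n_obs, n_var = adata.shape
    cell_mask = np.ones(n_obs, bool) if cell_mask is None else np.asarray(cell_mask)
    gene_mask = np.ones(n_var, bool) if gene_mask is None else np.asarray(gene_mask)
    if cell_mask.shape != (n_obs,) or gene_mask.shape != (n_var,):
        raise ValueError("mask length does not match dataset dimensions")
    if not cell_mask.any():
        raise ValueError("cell mask removes every cell")
    out = adata[cell_mask, :][:, gene_mask].copy()
    out.obsm.clear()
    out.obsp.clear()
    out.uns.pop("eigenvalues", None)
    compute_cell_metrics(out)
    return out
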