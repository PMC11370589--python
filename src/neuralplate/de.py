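"""Two-part (hurdle) differential expression between conditions, per region.

Expression for testing is log2(1 + median-normalized counts), the median taken
over the union of both groups so the two conditions share one scale.  Per gene
the model has two parts:

* detection — likelihood-ratio (G) test of equal detection probability on the
  2×2 detected/undetected table, with a two-sided Fisher exact fallback when
  any expected count is below 5;
* continuous — Welch t-test on the positive cells' log2 values, skipped when
  either group has fewer than 3 positive cells.

The component p-values are combined by converting each to a chi-square(1)
deviate and referring the sum to chi-square(2) (the hurdle combination; with
one component skipped, that component contributes nothing and df drops to 1).
The effect size is the difference of zero-inflated means on the log2 scale,
pi_b * mu_b − pi_a * mu_a — the closed-form analogue of the hurdle-model
log2 fold change — reported alongside the empirical log2 fold change over all
cells.

A gene is significant in a region when FDR < 0.001 and |effect| > 0.24; genes
significant somewhere propagate to additional regions where p < 0.001 and
|effect| > 0.10, with genes summarized by region combination
(FB-MB-HB, FB-MB, …, single regions).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

P_FLOOR = 1e-300


def log2_normalized(counts_a: sp.spmatrix, counts_b: sp.spmatrix):
    """log2(1 + median-normalized counts), joint median over both groups."""
    A = sp.csr_matrix(counts_a, dtype=np.float64)
    B = sp.csr_matrix(counts_b, dtype=np.float64)
    lib = np.concatenate(
        [np.asarray(A.sum(axis=1)).ravel(), np.asarray(B.sum(axis=1)).ravel()]
    )
    med = np.median(lib)

    def _scale(M, libs):
        M = sp.diags(med / np.maximum(libs, 1)) @ M
        M = np.asarray(M.todense())
        return np.log2(M + 1)

    na = A.shape[0]
    return _scale(A, lib[:na]), _scale(B, lib[na:])


def _g_test_2x2(k1, n1, k2, n2):
    """Vectorized likelihood-ratio test of equal detection probability."""
    k1, k2 = k1.astype(float), k2.astype(float)
    tot_pos = k1 + k2
    tot = float(n1 + n2)
    table = np.stack([k1, n1 - k1, k2, n2 - k2])
    row = np.stack([tot_pos, tot - tot_pos])
    expected = np.stack(
        [row[0] * n1 / tot, row[1] * n1 / tot, row[0] * n2 / tot, row[1] * n2 / tot]
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        term = table * np.log(table / expected)
    term[~np.isfinite(term)] = 0.0
    G = 2 * term.sum(axis=0)
    p = stats.chi2.sf(G, df=1)
    small = expected.min(axis=0) < 5
    return p, small


def hurdle_test_matrix(Xa: np.ndarray, Xb: np.ndarray):
    """Vectorized hurdle test over all genes.

    ``Xa``/``Xb`` are cells × genes log2-normalized matrices.  Returns a frame
    with columns effect, p, lfc, p_detection, p_continuous (NaN where a part
    was skipped); genes with both parts skipped have p = NaN.
    """
    na, nb = Xa.shape[0], Xb.shape[0]
    if na < 20 or nb < 20:
        raise ValueError("both groups need at least 20 cells")
    pos_a, pos_b = Xa > 0, Xb > 0
    ka, kb = pos_a.sum(axis=0), pos_b.sum(axis=0)

    # detection part: skip when pooled detection is degenerate (no information)
    degenerate = (ka + kb == 0) | (ka + kb == na + nb)
    p_det, small = _g_test_2x2(ka, na, kb, nb)
    for j in np.flatnonzero(small & ~degenerate):
        table = [[int(ka[j]), na - int(ka[j])], [int(kb[j]), nb - int(kb[j])]]
        p_det[j] = stats.fisher_exact(table).pvalue
    p_det[degenerate] = np.nan

    # continuous part: Welch t on positive cells
    def _pos_stats(X, mask, k):
        s = np.where(mask, X, 0.0).sum(axis=0)
        ss = np.where(mask, X**2, 0.0).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            m = s / k
            v = (ss - k * m**2) / np.maximum(k - 1, 1)
        return m, np.maximum(v, 0.0)

    mu_a, va = _pos_stats(Xa, pos_a, ka)
    mu_b, vb = _pos_stats(Xb, pos_b, kb)
    cont_ok = (ka >= 3) & (kb >= 3)
    p_cont = np.full(Xa.shape[1], np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        se2 = va / np.maximum(ka, 1) + vb / np.maximum(kb, 1)
        t = (mu_b - mu_a) / np.sqrt(se2)
        df = se2**2 / (
            (va / np.maximum(ka, 1)) ** 2 / np.maximum(ka - 1, 1)
            + (vb / np.maximum(kb, 1)) ** 2 / np.maximum(kb - 1, 1)
        )
    valid = cont_ok & np.isfinite(t)
    p_cont[valid] = 2 * stats.t.sf(np.abs(t[valid]), df[valid])
    zero_var = cont_ok & ~np.isfinite(t)  # identical positives in both groups
    p_cont[zero_var & (mu_a == mu_b)] = 1.0

    # combine: chi2(1) deviates summed, df = number of available parts
    have_det = np.isfinite(p_det)
    have_cont = np.isfinite(p_cont)
    chi = np.zeros(Xa.shape[1])
    dof = np.zeros(Xa.shape[1], dtype=int)
    chi[have_det] += stats.chi2.isf(np.clip(p_det[have_det], P_FLOOR, 1), 1)
    dof[have_det] += 1
    chi[have_cont] += stats.chi2.isf(np.clip(p_cont[have_cont], P_FLOOR, 1), 1)
    dof[have_cont] += 1
    p = np.full(Xa.shape[1], np.nan)
    usable = dof > 0
    p[usable] = stats.chi2.sf(chi[usable], dof[usable])

    pi_a, pi_b = ka / na, kb / nb
    effect = pi_b * np.where(kb > 0, mu_b, 0.0) - pi_a * np.where(ka > 0, mu_a, 0.0)
    lfc = Xb.mean(axis=0) - Xa.mean(axis=0)
    return pd.DataFrame(
        {
            "effect": effect,
            "p": p,
            "lfc": lfc,
            "p_detection": p_det,
            "p_continuous": p_cont,
        }
    )


def hurdle_test(ds_a: AnnData, ds_b: AnnData, gene: str):
    """Hurdle effect (log2 scale) and p-value for one gene."""
    if gene not in ds_a.var_names or gene not in ds_b.var_names:
        raise KeyError(f"gene {gene!r} absent from dataset")
    Xa, Xb = log2_normalized(ds_a.layers["counts"], ds_b.layers["counts"])
    j_a = ds_a.var_names.get_loc(gene)
    j_b = ds_b.var_names.get_loc(gene)
    res = hurdle_test_matrix(Xa[:, [j_a]], Xb[:, [j_b]])
    return float(res["effect"][0]), float(res["p"][0])


def regional_de(
    ds_control: AnnData,
    ds_treated: AnnData,
    regions=("forebrain", "midbrain_r1", "hindbrain"),
    fdr_max: float = 0.001,
    effect_min: float = 0.24,
    propagate_effect: float = 0.10,
    min_cells: int = 20,
) -> pd.DataFrame:
    """Per-region hurdle DE with significance and cross-region propagation.

    Midline cells are excluded by the default region list (low cell numbers).
    Returns a tidy frame with one row per (gene, region) and flags
    ``significant`` (FDR < ``fdr_max`` and |effect| > ``effect_min``) and
    ``propagated`` (p < ``fdr_max`` and |effect| > ``propagate_effect`` and
    significant in at least one region).
    """
    if not ds_control.var_names.equals(ds_treated.var_names):
        raise ValueError("control and treated datasets must share gene order")
    frames = []
    for region in regions:
        ma = (ds_control.obs["region"] == region).to_numpy()
        mb = (ds_treated.obs["region"] == region).to_numpy()
        if ma.sum() < min_cells or mb.sum() < min_cells:
            logger.warning("region %s: fewer than %d cells; skipped", region, min_cells)
            continue
        Xa, Xb = log2_normalized(
            ds_control.layers["counts"][ma], ds_treated.layers["counts"][mb]
        )
        res = hurdle_test_matrix(Xa, Xb)
        res.index = ds_control.var_names
        ok = res["p"].notna()
        res["fdr"] = np.nan
        res.loc[ok, "fdr"] = multipletests(res.loc[ok, "p"], method="fdr_bh")[1]
        res["region"] = region
        res["direction"] = np.where(res["effect"] > 0, "up", "down")
        res["significant"] = (res["fdr"] < fdr_max) & (res["effect"].abs() > effect_min)
        frames.append(res.reset_index(names="gene"))
    if not frames:
        raise ValueError("no region had enough cells in both conditions")
    table = pd.concat(frames, ignore_index=True)

    sig_any = set(table.loc[table["significant"], "gene"])
    table["propagated"] = (
        table["gene"].isin(sig_any)
        & (table["p"] < fdr_max)
        & (table["effect"].abs() > propagate_effect)
    )
    return table


def region_combination_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Count up/down genes per region combination (FB-MB-HB, FB-MB, … , HB).

    A gene belongs to the combination of regions where it is significant or
    propagated, split by direction in those regions.
    """
    short = {"forebrain": "FB", "midbrain_r1": "MB", "hindbrain": "HB"}
    hits = table[table["significant"] | table["propagated"]]
    rows = []
    for (gene, direction), grp in hits.groupby(["gene", "direction"]):
        regs = sorted(
            {short.get(r, r) for r in grp["region"]},
            key=lambda s: ["FB", "MB", "HB"].index(s) if s in ("FB", "MB", "HB") else 9,
        )
        rows.append({"gene": gene, "direction": direction, "combination": "-".join(regs)})
    if not rows:
        return pd.DataFrame(columns=["combination", "direction", "n_genes"])
    df = pd.DataFrame(rows)
    return (
        df.groupby(["combination", "direction"])
        .size()
        .rename("n_genes")
        .reset_index()
        .sort_values(["combination", "direction"])
        .reset_index(drop=True)
    )
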