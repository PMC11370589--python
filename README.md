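# neuralplate

Spatial and temporal transcriptional cartography of the embryonic mouse
cranial neural plate from droplet scRNA-seq.

During cranial neural tube closure (E7.5–E9.0), the neural plate is patterned
along two orthogonal spatial axes — anterior–posterior (AP: forebrain,
midbrain/r1, hindbrain) and mediolateral (ML: ventral midline / floor plate
out to the lateral borders) — while simultaneously progressing in
developmental time. `neuralplate` reconstructs all three axes from single-cell
transcriptomes alone and builds a catalogue of spatially patterned genes and
gene modules, then quantifies how a perturbation (pharmacological activation
of SHH signalling) remodels that catalogue region by region. The package is
aimed at developmental biologists analysing axis-patterned epithelia with
scRNA-seq, and every stage is validated end-to-end on a ground-truthed
synthetic tissue generator shipped with the package.

## The method

1. **QC** — per-cell filters (library size > 1,000 UMIs, mitochondrial
   fraction < 20%, library-complexity residual > −0.1 from the OLS fit of
   log10 genes on log10 UMIs), then a kernel-density fit to log10 library
   size detects a low-quality mode, and whole fine clusters (Leiden on a k=8
   kNN graph) are removed by a one-sided Z-test (p < 1e−10) of their mean
   library size against the high-quality mode.
2. **Embedding** — median-library normalization and ln(1+x); vst-style
   highly-variable-gene selection (top 3,000; mito/ribo/rare genes excluded,
   curated markers retained); optional cell-cycle regression on gene-set
   scores; PCA to 75% explained variance; exact kNN graphs (k=30), unit
   weights for clustering and adaptive-Gaussian weights
   exp(−d²/σᵢ²) for diffusion.
3. **Axes** — a diffusion map of the cell–cell Markov matrix M = D⁻¹W; the
   component count is the largest eigengap within the first 40 eigenvalues;
   multiscale space rescales components by λ/(1−λ). Which diffusion
   component (DC) tracks which axis is established by correlation with
   marker gene sets, never assumed. Within one region, DC0 is the temporal
   axis (validated against somite stage); on the late-stage pooled tissue,
   leading DCs recover the AP and ML axes.
4. **Spatially patterned genes** — a local autocorrelation statistic
   H = Σ_{i≠j} w_ij x_i x_j (a z-normalized Moran's I) on three latent
   spaces (AP DC alone, ML DC alone, multiscale space), with analytic
   randomization-null moments; genes pass at ln-expression range > 1,
   BH FDR < 1e−5 and Z ≥ 10 (or a knee-point threshold).
5. **Trends and modules** — MAGIC-style graph-diffusion imputation (k=5,
   t=3), penalized cubic-spline trends over 500 bins along an axis,
   trend clustering (k=20 kNN graph + Leiden), and Ward hierarchical
   clustering of the gene–gene correlation matrix with a knee-point default
   cut and fixed cuts at linkage distances 10/6/4.
6. **Differential expression** — a two-part hurdle test per gene and region
   (detection G-test/Fisher + Welch t on detected cells, combined as
   χ²(2)); significant at FDR < 0.001 and |hurdle effect| > 0.24 on log2,
   propagated to further regions at p < 0.001 and |effect| > 0.10.

## Worked example

The `all` command simulates the reference synthetic tissue (2,000 cells,
500 genes, six somite stages, 15% planted low-quality cells, 120 spatially
patterned genes) and runs every stage against the generator's ground truth:

```bash
neuralplate all --out run/
```

prints (seed 0):

```json
{
  "qc":      {"n_input": 2000, "n_kept": 1700, "sensitivity": 1.0, "false_removal": 0.0},
  "axes":    {"n_selected_dcs": 2, "ap_dc": 0, "ml_dc": 2,
              "spearman_ap": 0.950, "spearman_ml": 0.942},
  "spatial": {"n_selected": {"dc_ap": 117, "dc_ml": 139, "multiscale": 143},
              "sensitivity_multiscale": 0.99, "false_discovery_fraction": 0.0},
  "regions": {"accuracy": 0.99},
  "de":      {"n_significant_up": 20, "n_significant_down": 13, "power": 1.0}
}
```

Reading this: all 300 planted low-quality cells were removed with no good
cells lost; diffusion component 0 of the late-stage tissue orders cells along
the true AP axis (Spearman 0.95) and DC2 along the ML axis (0.94); the
autocorrelation screen recovers ~99% of the truly patterned genes with no
false discoveries among null genes; region classification is ~99% accurate;
and the hurdle test finds every planted two-fold treatment effect
(20 up-regulated medial-program genes, 13 down-regulated lateral genes)
in all three regions.

The same stages are available as library calls (`simulate_tissue`, `run_qc`,
`embed_diffusion`, `local_autocorrelation`, `regional_de`, …) and as
scikit-learn-style estimators (`DiffusionMapEmbedding`,
`AbsorptionClassifier`, `SpatialAutocorrelation`, `GraphDiffusionImputer`)
that expose `fit`/`transform`/`predict_proba` and compose with sklearn
tooling. Individual CLI stages (`simulate`, `qc`, `embed`, `classify`,
`axes`, `spatial`, `trends`, `de`) read and write a single-file `.h5ad`
container plus TSV/JSON artifacts.

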