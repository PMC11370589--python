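# Methods

This note documents the models and procedures implemented in `neuralplate`,
the assumptions behind them, the parameters that matter, and the choices made
where the design was genuinely open.

## Data model

The dataset container is `anndata.AnnData`: raw UMI counts in
`layers["counts"]` (cells × genes, sparse), derived expression in
`layers["normalized"]` (ln of median-library-normalized counts, pseudocount
1) and `layers["imputed"]`, embeddings in `obsm` with diffusion eigenvalues
in `uns`, and neighbor graphs in `obsp`. On disk the 10x convention
(genes × cells MatrixMarket triplet) is transposed on load. Subsetting
deliberately drops embeddings and graphs: normalization and geometry are
sample-set dependent (the median library changes with the cell set), so
every regional or stage subset is re-normalized and re-embedded rather than
sliced — this prevents stale-geometry bugs and mirrors how the per-region
analyses are meant to be run. Mitochondrial and ribosomal genes are
recognized by mouse symbol prefixes (`mt-` case-insensitively; `Rps`/`Rpl`),
configurable at the module level. Gene symbols are treated as opaque
strings; no alias resolution is attempted.

## Synthetic tissue generator

The generator is first-class, tested code: it defines the reference conditions
under which every downstream stage is validated.

Each cell carries latent coordinates (ap, ml, t) ∈ [0,1]³; regions derive
from fixed breakpoints (ap < 0.33 forebrain, < 0.66 midbrain/r1, else
hindbrain; ml < 0.08 midline). Patterned genes follow smooth templates:
logistic fronts along AP centred near the region breakpoints (sharpness
0.03–0.08, both orientations), monotone gradients or Gaussian bumps along
ML, products of AP fronts and medial weighting for dual-axis genes, and
monotone ramps in time. Templates map to rates via `fold^(template − 0.5)`
with an 8-fold default dynamic range — developmental markers of this kind
(Otx2, Hox genes, Shh targets) are near on/off, so 8-fold is conservative
realism. Medial-program templates saturate to 1 inside the midline region:
the floor plate is a discrete, SHH-induced identity whose medial program is
maximally active there, not merely the end of a gradient; without this the
midline is just a thin slice of a continuum and no classifier (or biologist)
could call it a cell type. Each region additionally has 6 discrete marker
genes (~8-fold, on in that region only).

Counts are Gamma–Poisson (negative binomial) with Var = m + 0.3·m² —
dispersion 0.3 is typical droplet overdispersion — around
mean = libsize_c × relative rate, with log-normal library sizes (median
≈ 5,000 UMIs, σ_ln = 0.35). Low-quality cells emulate the stressed/leaky
phenotype seen in droplet data: library sizes shrunk to 25% (a "low to
moderate" mode that survives the hard UMI cutoff), a dedicated 10-gene
stress program boosted ~20-fold so that it dominates roughly a third of the
library (this is what makes these cells cluster by quality rather than by
position), doubled mitochondrial/ribosomal load (kept below the 20% filter),
and a mild (α = 0.25) collapse of expression toward the 50 most abundant
genes. The treatment condition multiplies medial-program gene rates by the
effect size (default 2.0) and divides lateral-program rates by it, within
configurable regions; ground-truth per-region log2 fold changes are exported
with the dataset.

Ground truth (cell coordinates, regions, low-quality flags, gene categories,
perturbed genes) is returned as a sidecar table and never written into the
`obs` fields the pipeline reads, so no stage can leak it.

What the generator does **not** emulate: ambient RNA, barcode collisions and
doublets (upstream tools' concern), batch/replicate effects beyond seeding,
burst-like transcriptional noise, and the 20,000-gene scale of real data.
Passing tests therefore demonstrate correctness of the algorithms under
realistic but idealized structure, not full-scale performance on real
tissue.

## Quality control

The complexity filter regresses log10(genes detected) on log10(UMIs) by OLS
over cells passing the other two filters and removes cells with residual
< −0.1; the fit is iterated to a fixed point (remove, refit, repeat) so the
filter is idempotent — a single fit is not, because removing outliers shifts
the refitted line.

KDE mode detection uses a Gaussian KDE (Scott bandwidth) of log10 library
size on a 512-point grid. Local maxima are pruned by two robustness rules
chosen here: adjacent maxima without a genuine valley between them (saddle
density above 95% of the smaller peak) are merged — sampling wiggles on a
smooth unimodal distribution have shallow saddles — and a mode's basin must
hold ≥ 2% of cells. If the upper mode holds under 25% of cells it is treated
as a tail bump and the distribution as unimodal: using a minority upper tail
as the "high-quality" reference would purge the dataset. Unimodal is a valid
outcome and skips cluster-level filtering.

Cluster-level removal: Leiden fine clusters (k = 8 unit graph) are tested by
a one-sided two-sample Z of the cluster's mean log10 library size against
the high mode's (mean, sd, n); clusters with p < 1e−10 on the low side are
removed wholesale — retaining cells by phenotypic similarity rather than a
hard threshold. The Z-test uses library size only; mean gene count per
cluster is logged as a secondary diagnostic.

## Embedding

HVG ranking follows the variance-stabilizing approach: a quadratic trend of
log10 variance on log10 mean (standing in for the loess of the reference
implementation), per-entry standardization clipped at √n, and ranking by the
variance of the clipped values. Cell-cycle removal regresses each gene on
the *raw* mean-expression score of each cell-cycle gene set; the raw score
is linear in an additive cell-cycle factor, so OLS removes it exactly in the
noiseless limit, whereas the z-normalized score (used everywhere else for
scoring) is nonlinear through the per-cell variance. Residuals are
re-centred to preserve per-gene means. PCA keeps the smallest number of
components reaching 75% cumulative explained variance (exact SVD below
5,000 cells, seeded randomized SVD above; genes centred, not scaled to unit
variance). kNN graphs are exact (brute force, ties broken by lower cell
index for determinism); the adaptive-Gaussian kernel uses
σᵢ = distance to the ⌈k/3⌉-th neighbor, recorded in configuration.

## Clustering and classification

Community detection converts the kNN adjacency to the shared-neighbor
Jaccard graph (w_ij = |N_i ∩ N_j| / |N_i ∪ N_j| over all pairs sharing a
neighbor) before seeded Leiden modularity maximization. The densification
matters: on a sparse unit kNN graph, modularity provably prefers shattering
a large well-separated community (two 200-cell blobs: modularity 0.56 split
five ways vs 0.50 for the true 2-block partition), while on the Jaccard
graph communities are near-cliques and are recovered whole.

Signature scores: s_c = mean normalized expression over positive genes minus
mean over negatives, z-normalized against an analytic random-signature null
drawn from the cell's own gene-expression distribution (per-cell mean μ_c
and variance v_c): with negatives, Var = v_c(1/m⁺ + 1/m⁻) and the null mean
is 0; with positives only, z = (s_c − μ_c)/√(v_c/m⁺). A Monte-Carlo
random-signature oracle backs this in the tests. Genes absent from the
dataset are dropped at use time with a warning; a signature with no usable
positive genes is a flagged missing column, and classification refuses to
run with one.

Cell typing is a four-step loop: (1) preliminary labels per fine cluster by
maximum mean signature (ties logged, first wins); clusters come from the
finest Leiden resolution on a fixed ladder (1, 2, 4, 8) at which every
signature still dominates at least one cluster — coarse clusters contaminate
the preliminary sets and hence the thresholds of step (2), where type
thresholds are the 20th percentile of own-type scores among preliminarily
labeled cells, and a cell trains for its type only if it exceeds its own
threshold and stays below all others'. (3) The absorbing Markov chain: the
row-stochastic transition matrix of the adaptive-Gaussian k=30 graph with
training cells absorbing; the absorption system (I − Q)B = R is solved by a
sparse direct solve (unreachable cells get uniform rows with a warning), and
(4) each cell takes the label with maximal absorption probability. The
classifier is exposed as a scikit-learn estimator (`AbsorptionClassifier`,
LabelPropagation-style `y = −1` for unlabeled) and is invariant to graph
weight rescaling.

## Diffusion axes

The Markov matrix is eigendecomposed through its symmetric conjugate
D^{−1/2}WD^{−1/2}; the stationary eigenvector is dropped, components are
labeled DC0, DC1, … by descending eigenvalue, and a deterministic sign
convention (largest-magnitude entry positive) makes runs reproducible.
Anisotropic density normalization (α = 1) is available but off by default —
the minimal construction is the documented one. Disconnected graphs are
handled per giant component with NaN coordinates elsewhere, with a warning.
The eigengap rule returns the component count preceding the largest gap in
the first 40 eigenvalues (ties to the smaller count). The mapping of DCs to
tissue axes is always established by Spearman correlation with
marker-derived signature scores; on the down-scaled reference tissue the
eigengap typically keeps 2 components while the ML axis sits on DC2, so the
latent space used for the multiscale gene screen is extended to cover the
marker-identified axis DCs whenever the eigengap count falls short of them.

## Spatially patterned gene selection

Weights: adaptive-Gaussian kNN graph on the latent space, symmetrized
(elementwise max), row-normalized, then re-symmetrized as (W + Wᵀ)/2, zero
diagonal. With per-gene standardized expression x the statistic
H = Σ_{i≠j} w_ij x_i x_j equals S₀·I with I Moran's I and S₀ = Σw_ij, so the
null moments under random assignment of expression values to cells are the
classical randomization moments of Moran's I: E[H] = −S₀/(n−1), and Var[H]
from the S₁/S₂ formula with the per-gene kurtosis of the standardized
values. The cruder i.i.d. approximation (E = 0, Var = 2Σ_{i<j}w²) is biased
by tens of percent at n ≈ 300 and fails a 10,000-permutation oracle at the
10% tolerance the tests enforce; the randomization moments pass it.
Constant genes get Z = 0, p = 1. One-sided normal p-values are BH-adjusted
across genes. Selection applies, in order: ln-expression range > 1 (computed
on the log-normalized layer — imputed values are never used for
statistics), FDR < 1e−5, and Z ≥ 10 or a knee-point threshold on the sorted
Z curve (both modes implemented; the fixed 10 is the default).

The knee point of a curve is the index of maximum perpendicular distance to
the chord joining its endpoints (ties to the smallest index; a straight
line returns 0 with a warning).

## Trends and modules

Imputation is diffusion smoothing: imputed = (D⁻¹W)ᵗ · normalized with
k = 5, t = 3, exposed as the `GraphDiffusionImputer` transformer; it is
display/trend-only. Trends are penalized cubic B-splines (8 knots at axis
quantiles, second-difference penalty, per-gene penalty weight chosen by
closed-form GCV over a fixed log-spaced grid — deterministic and solved for
all genes simultaneously per λ), evaluated at 500 equally spaced axis
values. Trend clustering z-normalizes each trend, builds a k = 20 kNN graph
and runs the Leiden clustering above; labels are ordered by mean peak
position so anterior-peaked clusters come first. kNN-graph communities
cannot be smaller than k, so k must sit below the smallest expected cluster
size — k = 20 suits catalogues with ≳30 genes per cluster, and the tests
cover both regimes.

Gene modules: each selected gene's feature vector is its row of the
gene–gene Pearson correlation matrix (log-normalized layer; constant genes
dropped with a warning); Ward linkage on Euclidean distances; labels at
fixed linkage-distance cuts (10/6/4 by default, configurable since heights
grow with gene count) and at a data-driven default cut — the knee of the
*mean* within-cluster pairwise correlation as a function of cluster count.
The mean, not the median, drives the knee: an under-merged cut dilutes
within-cluster similarity with cross-module pairs, which the mean registers
immediately while the median ignores contamination below 50%. The median at
the chosen cut is reported alongside. Manual exclusion of clusters (e.g.
trend clusters dominated by another axis's identity) is supported as a
configuration list, not automated.

## Hurdle differential expression

Expression for testing is log2(1 + median-normalized counts) with the
median over the union of both groups. Per gene: a detection part
(likelihood-ratio G-test on the 2×2 detected table; two-sided Fisher exact
when any expected count < 5; skipped when pooled detection is degenerate)
and a continuous part (Welch t on detected cells' values; skipped when
either group has < 3 positive cells). The parts are combined by converting
each p to a χ²(1) deviate and referring the sum to χ²(df = number of
available parts) — the hurdle combination, which sums the component test
statistics rather than Fisher's −2·log p (that would be χ²(4) for two
parts, and treating it as χ²(2) would be wildly anticonservative). The
effect size is the difference of zero-inflated means on log2 scale,
π_b·μ_b − π_a·μ_a, the closed-form analogue of a hurdle-model log2 fold
change; the empirical log2 FC over all cells is reported alongside. The
test is calibrated: over 20,000 null tests the rejection rate at p < 0.001
sits inside the 95% binomial interval (the acceptance script recomputes
this). Covariate adjustment (replicate effects) is out of scope.

Regional analysis runs the test per gene in each of forebrain, midbrain/r1
and hindbrain (midline excluded by default for low cell numbers —
configurable), BH-adjusts within region, flags significance at FDR < 0.001
and |effect| > 0.24, propagates genes significant somewhere to regions where
p < 0.001 and |effect| > 0.10, and summarizes genes by region combination
(FB-MB-HB, FB-MB, …, single regions) and direction.

## Problem sizes and numerical choices

The reference validation runs at 2,000 cells × 500 genes (120 truly
patterned genes, 15% planted low-quality cells, six stages × two
replicates), a scale at which the full pipeline completes in seconds and
every stage's behaviour is scored against ground truth; the null
calibration uses 20,000 tests (800 cells × 10,000 genes split at random).
Tolerances: absorption matrices match a dense solve to 1e−6; eigen
reconstruction to 1e−8; signature and imputation identities to 1e−10–1e−12;
analytic autocorrelation Z within 10% of a 10,000-permutation z-score for
|Z| ≤ 6. All randomness is seeded; graph construction and eigen-sign
conventions are deterministic, so repeated runs are bit-identical.

## Known limitations

- The generator's spatial templates are smooth and low-dimensional; real
  expression programs have richer covariance, so sensitivity estimates here
  are optimistic upper bounds.
- The eigengap rule is scale-sensitive: on small tissues it under-counts
  informative components, which is why axis↔DC identification is
  marker-driven and the multiscale space is extended to cover identified
  axes.
- The hurdle test omits replicate-level covariates and shrinkage; with few
  biological replicates its p-values reflect cell-level, not embryo-level,
  variation.
- The published full-scale catalogue sizes (hundreds of spatial genes from
  ~20,000 measured) are not reproducible at the down-scaled reference size;
  the pipeline reproduces thresholds, shapes and operating characteristics
  instead.
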