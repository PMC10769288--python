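# Methods

This note documents the models, numerical choices and open design
decisions behind `cortical_continuum`, in the spirit of a package-level
methods appendix. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Synthetic data generators

### Continuum simulator

Cells and genes carry 1-based normalized rankings `p_i = i/Nc` and
`p_j = j/Ng` (the index origin matters: both rankings live in (0, 1], and
a cell whose ranking equals a gene's ranking sits on the expression
ridge). Expected expression is the Gaussian kernel

    lambda_ij = exp(-((p_i - p_j) / epsilon)^2)

and counts are drawn as `s * Poisson(lambda_ij)` — the scale sits outside
the distribution, so counts are integer multiples of `s`. The alternative
reading `Poisson(s * lambda)` is deliberately rejected: with the scale
outside, the variance of a count is `s^2 * lambda`, which is what the
formula as written implies. Defaults are Nc = 600, Ng = 60, s = 100 and
epsilon in [0.1, 1], matching the configuration the downstream tests
exercise.

### Discrete-type simulator

`lambda_ij = 1` when cell i's type equals gene j's marker type, else
`epsilon` (leaky expression in [0, 1]); counts are again
`s * Poisson(lambda)`. To impose an order on the types, the first
`shared_markers` markers of each type are also expressed (`lambda = 1`) in
the *next* type — sharing chains A→B→C and does not wrap around from the
last type. Defaults: 3 types × 20 markers × 200 cells, 6 shared markers.

### Archetype mixture

A positive control for triangularity: three profiles over the gene panel
(each archetype owns a third of the genes at a high rate), cells are
uniform-Dirichlet convex combinations, counts are Poisson. Because the
planted geometry is *linear* in the mixture weights, it survives any
affine per-gene transform (z-scoring) but is bent by logarithms — see
"Normalization and triangularity" below.

### Cortical section emulator

Emulates the structure of an imaging-based spatial transcriptomics
section without modelling optics, decoding or segmentation:

* a quartic pial curve `y = f(x)` over a 6 mm tangential domain, with `y`
  in microns increasing away from the pia;
* anchor (meningeal-like) cells on the curve with 5 µm jitter, plus a 5%
  fraction of ectopic marker-positive cells at 300–500 µm depth so the
  iterative pruning in the geometry module has genuine outliers to remove;
* subclasses (L2/3, L4, L5, L6) drawn uniformly within literature-scale
  depth bands; subclass marker genes expressed in-band;
* three identity-gene sets (A/B/C, 15 genes each) whose rates follow
  overlapping Gaussian depth profiles centred at 150/210/280 µm
  (width 45 µm) inside L2/3 — the planted upper/middle/lower zonation;
* a V1-like tangential interval (1.5–3.5 mm) with a 5-fold enriched "on"
  marker and 5-fold depleted "off" marker;
* 8 IEG-like genes, upshifted by a planted log2 fold-change (default 2.0)
  in dark-reared samples; B/C identity genes mildly down-regulated in DR
  (×0.7 / ×0.6) so the redistribution analyses have signal;
* per-cell volumes (log-normal around 300), expected counts proportional
  to volume and to a per-sample log-normal batch factor (forcing the
  normalization to actually do work), blank counts at a ~1.5% rate, and a
  2% planted QC-failure fraction (bad volume, or low counts with 25%
  blank rate) so every QC threshold is exercised;
* eight samples, four per rearing condition, mirroring a 4-vs-4 replicate
  design.

What the emulator does *not* reproduce: realistic gene–gene covariance
beyond the planted gradients, segmentation errors, spatial autocorrelation
of technical noise, or a genuine cell-type hierarchy. Passing tests
therefore demonstrate that the algorithms recover planted structure under
Poisson noise and batch/volume confounders — not that they are robust to
every artefact of real imaging data.

## Preprocessing

MERFISH-style normalization: divide by segmented volume; rescale each
sample so the mean per-cell total over *non-excluded* genes equals 250
(excluding the IEG panel from the size factors prevents a
condition-specific activity surge from deflating all other genes in the
affected samples); then log10(x+1) and per-gene z-scores. The log base
is fixed to 10 for both modalities. Per-gene z-scoring is pooled across
samples (not within-sample); this keeps between-sample contrasts
interpretable and is recorded in the matrix provenance. The blank-rate
denominator is `blanks + gene transcripts`.

snRNA-seq: per-cell rescale to 10,000, pseudo-count 1, log10, z-scores.
All-zero cells cannot be size-normalized and are dropped with a warning.

HVG selection computes the variance/mean ratio on CP10k values (constant
under Poisson sampling), bins genes into equal-count deciles of mean
expression (stable sort; ties fall in the lower bin) and takes the top
30% ratio per bin. Marker derivation is one-vs-rest Wilcoxon (exact below
25 per group, tie-corrected normal above), BH-FDR, fold change on
linear-scale means with pseudo-count 1, and a >30% expressing-fraction
requirement in the up-regulated type.

## Curved cortical geometry

The pial curve is a single-valued degree-4 polynomial `y = f(x)`; sections
whose pial surface folds in `x` must be pre-rotated (documented
precondition). Fitting iterates: fit on retained anchors → compute anchor
depths → drop anchors deeper than 0.5 × (95th-percentile depth) → refit.
Two numerical guards matter in practice: the pruning threshold never drops
below the 1 µm curve-sampling resolution, and iteration stops when two
successive curves differ by < 1 µm over the domain — otherwise, once all
genuine outliers are gone, the threshold would chase the anchors' own
jitter and prune the set to nothing.

Depth is the unsigned distance to the nearest curve point (dense 1 µm
sampling, KD-tree, parabolic refinement of the squared distance, accurate
to ≪ 0.1 µm); tangent is the arc length to the foot point (trapezoidal
integration at 1 µm steps). V1 is the maximal contiguous tangential run
where the kernel-smoothed (Gaussian, 100 µm bandwidth) enrichment marker
exceeds its tangential median while the depletion marker falls below its
own. The median-threshold rule is this package's reconstruction of a
qualitatively described marker-based localization; with a median
threshold the recovered interval is unbiased when V1 spans about half the
section and widens by roughly one smoothing bandwidth per side when it
spans less. Normalized tangential coordinates are `(t - tm)/(tl - tm)`,
so 0 and 1 are the V1 ends and values outside [0, 1] are flanking cortex.

## Hybrid graphs and label transfer

Expression and spatial kNN graphs use a shared-neighbour kernel: edge
(i, j) exists when either cell is in the other's k nearest neighbours,
with weight `(1 + |N(i) ∩ N(j)|) / (1 + k)`. The kernel form is this
package's choice (the upstream description delegates it to library
defaults). The hybrid weight is the convex blend
`w·expression + (1-w)·spatial` on the union of edge sets, equal weighting
by default. Leiden (RB-configuration modularity, resolution 1.0) requires
an explicit seed.

Label transfer assigns each query the modal label of its k nearest
reference cells (k = 100 for class level, 30 for subclass level), with
ties broken by the single nearest reference neighbour. The abstention
rule is computed in the *joint* reference+query pool: a query whose k
nearest pool neighbours contain ≤ 2 reference cells is labelled "NA" —
the signature of a locally failed integration.

## Archetypal analysis and the t-ratio

PCHA minimizes ‖X − XCS‖² with C and S column-stochastic (archetypes are
convex combinations of cells; cells are convex combinations of
archetypes), `delta = 0`, FurthestSum initialization, convergence at
relative loss change < 1e-6. In the 2-D / 3-archetype case — the case
this package actually uses — the S-subproblem is solved exactly by
closed-form point-to-triangle projection and the archetype positions are
updated toward their unconstrained least-squares optimum with projection
back onto the data's convex hull and step damping; the generic case falls
back to projected gradient with simplex projection. Only `delta = 0` is
supported.

Because PCHA archetypes are convex combinations of the data, the PCHA
triangle is *inscribed* and the ratio hull/PCHA-triangle can exceed 1.
The t-ratio here therefore uses the **minimal-area enclosing triangle** of
the convex hull, which bounds the ratio in (0, 1] and makes "= 1" mean
"the hull is a triangle". Both triangles are reported. The minimal
enclosing triangle uses the classical flush-side property: for every hull
edge as the flush base, the area is minimized over the outward-normal
angles of the two remaining supporting lines (coarse 24×24 grid,
vectorized golden-section coordinate descent across all edges, Nelder-Mead
polish of the winner). On canonical shapes this reproduces the exact
answers (unit square → area 2, ratio 0.5; triangle → ratio 1; uniform
disc → π/(3√3)).

The permutation test shuffles each gene independently across all cells
and refits the PCA per shuffle (refit is the conservative choice; reusing
fixed loadings would make the null easier to beat). The p-value is the
add-one estimator, so its floor is 1/(1+n_shuffles).

### Normalization and triangularity

A convex mixture of archetype profiles is linear in the mixing weights,
so any *affine* per-gene transform (centering, z-scoring) preserves the
triangle, while a logarithm bends it: on log-transformed mixture data the
simplex becomes a curved sheet and the t-ratio drops even without noise.
Triangularity tests on simulated mixtures are therefore run on per-gene
standardized linear expression. (Real identity-gene panels are analysed
on whatever normalized layer the caller provides; the distinction only
matters when the planted geometry is exactly linear.)

### Stability

Archetype stability refits PCA+PCHA on random 80% subsamples of cells
and, separately, of genes (10 trials each). Subsample embeddings are
aligned to the full embedding by orthogonal Procrustes (over the shared
cells for gene subsampling), archetypes are matched over the 6 vertex
permutations, and displacement is reported as a fraction of the full
fit's minimum inter-archetype distance.

## ABC scores

`s = clip((z − P40(z)) / (P95(z) − P40(z)), 0, 1)` per gene set, then
`p = s / (s_a + s_b + s_c)`. Values below the 40th percentile clip to 0
rather than reflecting about it — a reflection (reading an absolute value
literally) would score strongly anti-correlated cells as archetypal,
contradicting the [0, 1] bounding intent. Cells with all three rescaled
scores zero get the uninformative (1/3, 1/3, 1/3). `max p > 0.6` flags
archetypal cells.

## Pseudotime

Diffusion pseudotime on a kNN graph (k = 50) in the top-50-PC space of
the z-scored identity genes, rooted at the minimum-PC1 cell, min-max
rescaled to [0, 1]; unreachable cells (disconnected graph) are flagged
rather than imputed. Gene pseudotime is the expression-weighted mean of
cell pseudotime, `T_g = Σ_c w_gc t_c` with `w_gc = x_gc / Σ_c' x_gc'`
computed on the non-negative log-normalized layer; it is affine-equivariant
in t and is conventionally computed once on a reference condition and
held fixed for cross-condition comparisons.

## Continuum-vs-discrete verdict

K-means over k ∈ [2, 6] in 10-PC space, k selected by maximal mean
silhouette, on the original and the within-type-shuffled matrix (PCA
refit after shuffling). Verdict "continuum" when shuffling raises the
silhouette at the shuffled-selected k by more than a margin (default
0.05) *and* that k equals the number of label groups; "discrete" when the
change stays within the margin; "ambiguous" otherwise. The margin is a
package choice, configurable.

## Redistribution and differential expression

* Density maps: equal square bins (default side 1.25 PC units, in the
  1–1.5 range that is robust for these embeddings), normalized to
  probability; the difference map sums to zero by construction.
* Jensen–Shannon: square-root distance, natural-log convention (maximum
  √(ln 2) ≈ 0.8326 for disjoint supports); base-2 available.
* Optimal transport: exact EMD between uniform empirical distributions
  under squared-Euclidean cost (Euclidean optional). Equal-size problems
  are solved as assignment problems (Hungarian algorithm); unequal sizes
  as the transportation LP (HiGHS). The coarse-grained vector field bins
  source cells and averages coupling-weighted displacement per bin.
* Pseudo-bulk DE: raw counts summed per (type, sample), CPM-normalized;
  genes kept when mean CPM > 10 in at least one (type, condition);
  two-sided independent-samples t-tests across sample-level CPM values;
  BH-FDR within each type; log2FC with a pseudo-count of 1 CPM on both
  sides (the offset is a package choice); DEG = FDR < 0.05 and
  |log2FC| > 1. Requires ≥ 2 samples per condition by construction —
  replicates, not cells, are the statistical units.
* Overlap enrichment: two-sided Fisher exact test on the 2×2 membership
  table over a fixed background; sample odds ratio ad/bc with a Haldane
  0.5 correction (flagged) when any cell is zero.
* Regulation groups: each identity gene gets a signed significance
  pattern over types A/B/C ('+', '−', '0'); the default pattern→group
  mapping (all-up; all-down; up in B&C only; down in B&C only; single
  type; mixed; plus "vision-independent" for '000') is a documented
  reconstruction and is replaceable via the `rule` argument.

## Problem sizes and determinism

Default analysis sizes — 600×60 simulator matrices, a ~10,700-cell
synthetic section, 1000-shuffle permutation tests, 500-point transport
problems — were chosen so that the full pipeline runs end-to-end in
minutes on a single CPU while keeping Monte-Carlo error well inside the
assertions' tolerances. Every stochastic operation takes an explicit
seed; the CLI refuses to run a stochastic stage without one, and the
manifests record inputs (SHA-256), parameters and library versions.

## Known limitations

* Only 3-archetype (triangular) geometry; no tetrahedra or higher
  polytopes.
* The pial curve must be single-valued in x (pre-rotate otherwise).
* No ambient-RNA correction, doublet detection, batch integration
  (e.g. Harmony) or UMAP visualization; integration embeddings are
  accepted as inputs where needed.
* The GEO loader (`io.load_gse190940`) reads a locally downloaded deposit
  only and no analysis or test depends on it.
* GO-term enrichment (an external web service in typical workflows) is
  out of scope; `overlap_enrichment` covers the in-package statistics.
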