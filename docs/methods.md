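# Methods

## Model

For each gene, expression is modelled as a log-linear function of tiled
chromatin accessibility. The gene's window spans a symmetric flank (default
250 kb) on either side of the gene body, tiled into contiguous,
non-overlapping bins of 500 bp anchored at `gene start − flank` (window
relative, not genome-grid aligned), so a window has
`2·flank/tile_size + ceil(gene_length/tile_size)` tiles. All coordinates are
0-based half-open; a fragment contributes Tn5 insertions at `start` and
`end − 1`; tiles overlapping a blacklist interval by ≥ 1 bp are zeroed.

Tile counts are divided by each cell's reads-in-TSS (a depth/quality
normaliser) and multiplied by the cohort median reads-in-TSS; the median
factor only keeps magnitudes comparable across datasets and cancels in the
subsequent per-tile min–max scaling, which is fitted on training cells and
applied unchanged (no clipping) to held-out cells. Expression is normalised
to counts per 10,000 by default (`scale_factor` exposes counts-per-million
for pipelines that use it). Genes are selected by a dispersion ranking of
log1p-normalised expression (a plumbing stand-in for heavier
variable-gene machinery) and filtered to ≤ 90% zero cells, with the boundary
kept inclusive.

The loss is the mean Poisson negative log-likelihood kernel plus an L2
penalty, `(1/N) Σ (exp(Xw+ε) − y(Xw+ε)) + α‖w‖²`, applied to the normalised
(generally non-integer) expression without integerisation. Optimisation is
full-batch Adam (lr 0.01, β = 0.9/0.999) on (w, ε) with w projected onto the
non-negative orthant after every step, so exact zeros are attainable and the
retained tiles are interpretable as positive regulators. Stopping is on
relative loss change (< 1e−6 by default, max 5,000 iterations); ε is floored
at log(1e−8) so an all-zero target converges instead of running to −∞.
A loss-change tolerance maps to a looser gradient tolerance: fits stopped at
tol 1e−10 show projected-KKT violations around 1e−6, which is what the KKT
tests check (active coordinates ≈ 0 penalised gradient, zero coordinates
non-negative gradient). Unconstrained α = 0 fits agree with an independent
IRLS GLM solver to better than 1e−3 per coefficient.

α is selected on a grid {0.01, 0.1, 1, 10, 100} by four-fold CV within the
75% training split (the scaler is refit per fold; folds warm-start along the
ascending-α path), scoring held-out unpenalised Poisson deviance and breaking
ties toward the larger α. The held-out quarter of cells is used once, for the
reported Spearman ρ (degenerate constant predictions report ρ = 0 with a
flag).

## Attribution and tile significance

For a linear predictor the Shapley value of tile t for profile x reduces to
`w_t (x_t − mean(X_·t))` with the mean over all training cells (one shared
background, not per cell type). Cell-type scores draw 50 training cells of
the type without replacement per iteration (re-drawn across 500 iterations),
average the pseudobulk profiles, and z-score the resulting per-tile values
within (gene, cell type); types with fewer than 100 cells are skipped. The
z-scores are standardised across tiles only — per-type panels are the
intended reading.

Tile significance zeroes `w_t` (rather than the accessibility column), so the
scaler and intercept are untouched, and compares absolute prediction errors
with and without the tile on held-out cells of each type with a one-sided
paired Wilcoxon signed-rank test (zero differences dropped; exact null for
n ≤ 25 without ties, else normal approximation with continuity correction);
`w_t = 0` gives p = 1 by convention. BH correction is applied across all
(gene, tile, cell type) tests of a run. Gene-linked tiles require model
ρ > 0.1, Shapley z > 0.5 and FDR < 0.001, and are ranked by the significance
p for enrichment–recall curves, since Shapley z-scores are not comparable
across gene models.

Comparisons between two predictors of the same cells use the
dependent-correlation t-test (t ~ T(n−3) built from the correlation triple
ρ₁₂, ρ₁₃, ρ₂₃), one-sided; method comparisons over genes use the signed-rank
test. The interaction-score comparison takes the max Shapley value across
tiles spanned by an interaction, filters both interacting and background
tiles to accessibility above the 10th percentile of the reference set,
matches the two accessibility distributions by subsampling within 10
quantile bins, and applies a one-sided Mann–Whitney U test per cell type.

## Variant enrichment

Variants are matched on three criteria: MAF bin (<0.01, 0.01–0.1, >0.1,
boundaries into the middle bin), LD block (non-overlapping intervals;
variants outside all blocks get a sentinel block and are logged), and
distance class. With f flank tiles per side, tiles [f, n−f) are "gene body",
the min(20, f) tiles immediately upstream of the gene body (strand-aware)
are "promoter-proximal" (10 kb at default tile size), the mirror set
"downstream", the rest "distal". Within each matched group g,
`enrichment_g = precision_g / probability_g` with precision the
causal/common ratio inside gene-linked tiles and probability the same ratio
across all tiles; groups average with equal weight (as the formulas are
written), then units (traits for GWAS, genes for eQTLs, groups for the
regulatory-database set). Groups with zero causal variants, zero common
variants, or zero common variants in linked tiles are excluded from the
average. Common variants are one shared background across traits; for gene
units both numerators and denominators are restricted to that gene's window.
Default PIP thresholds are 0.2 (GWAS) and 0.5 (eQTL), exposed as flags.
Uncertainty is a percentile bootstrap over units (1,000 iterations, 95% CI;
two-sided p for method differences as 2·min tail fraction, floored at
1/n_iter).

Two small-sample properties matter when reading enrichment values. First,
the matched estimate is not the raw placement factor: if causal variants are
placed with weight F on linked tiles occupying L of the n tiles in a class,
the expected matched enrichment is F·n/(F·L + n − L) per group — ≈ F only
when L ≪ n. Second, groups with very few common variants in linked tiles are
zero-truncated, biasing the ratio upward, so calibration studies use
enhancer placements and variant counts dense enough (thousands of common
variants per gene) that these effects are ~2%. Bootstrap coverage is
assessed with gene units because per-trait enrichments share one common
background whose sampling noise a trait bootstrap cannot see; gene windows
are disjoint, so gene units are independent and the measured 95%-CI coverage
of the exchangeable truth is ~0.92 over 500 simulated universes.

## Chromatin potential

Predicted and observed expression are smoothed over a k = 50 nearest-
neighbour graph (Euclidean in an LSI embedding of the scATAC counts: TF-IDF,
log1p, truncated SVD; self included, so k = 1 is the identity), filtered to
genes with strictly positive predicted–observed Spearman correlation
(filtering after smoothing), min–max scaled per gene over all cells, and
matched: for each cell the k = 10 cells with the highest Pearson correlation
between its predicted vector and their observed vectors define the arrow
target (their mean 2D layout position). Self-matches are allowed, so
stationary terminal states produce near-zero arrows. Arrows are averaged on
a 30×30 grid over the layout bounding box for display; cosine similarity
compares fields per cell and magnitude differences aggregate by cell type.

## Synthetic data

The generator emulates exactly the structure the model assumes: tile counts
are Poisson with per-(cell type, tile) rates scaled by log-normal per-cell
depth factors (σ = 0.35); reads-in-TSS is proportional to depth; a gene's
expression is Poisson with rate `exp(X_scaled·w* + ε*)` times an RNA depth
factor, where w* is sparse and non-negative (default five planted enhancer
tiles with weights U(1, 2), accessible at rate 2.0/cell in the expressing
type vs 0.05 elsewhere, background tiles at 0.2). Background genes stabilise
per-cell totals for the counts-per-10k normalisation. An overdispersion knob
switches to gamma–Poisson mixing for robustness experiments. Fragments can
be emitted as a 5-column TSV whose insertions reproduce the tile counts
exactly (insertions are paired into fragments; an odd leftover pairs with a
spacer position outside every window).

Variant universes place common variants uniformly over tiles and causal
variants with a configurable weight on the planted enhancer tiles, with MAF
drawn from one three-bin mixture for both sets (exchangeable at factor 1)
and LD blocks tiling each window. Trajectories put cells on a 1D pseudotime
with per-gene driver tiles whose accessibility follows a sigmoid switching
at t₀ ~ U(−0.2, 1.0) and expression following the same sigmoid `Δ` later —
log-linearly, matching the model family; a linear link would let the exp
convexity masquerade as a time shift. Switch times extend beyond both path
ends so expression profiles are informative everywhere; fully saturated
profiles otherwise match plateau cells at random and drag arrows toward the
centroid.

What the simulations do not emulate: genomic sequence content, peak
structure and co-accessibility, doublets, batch effects, negative (silencer)
regulation, and trans effects. Passing tests therefore demonstrate
correctness of the estimator and calibration of the statistics under the
model's own assumptions, not performance on real tissue.

## Problem sizes and numerical choices

The test and acceptance workloads use 2,000 cells × 200 tiles with five
planted enhancers for recovery (20 seeds; median held-out ρ ≈ 0.78, median
active-tile Jaccard 1.0 with "active" = coefficient above 25% of the max),
30 genes × 100 tiles with 4,000 common/400 causal variants per gene for
enrichment calibration, and 800-cell, 50-gene trajectories (Δ = 0.15,
mean cosine with the true direction ≈ 0.63) for the potential field. With no
planted lead (Δ = 0) the mean progression along the path is ≈ −3% of its
length — a small backward drift caused by shrinkage of the predictions'
dynamic range — which is the baseline against which the forward signal
should be read.

Known limitations: the support of w is not identifiable under L2 (hence the
relative-threshold reading of "active tiles"); Shapley values are the linear
approximation, exact only for the linear predictor, not the exponential
mean; enrichment ratios are undefined in sparse matched groups and such
groups are dropped rather than imputed; and the chromatin-potential
direction is meaningful only where the layout faithfully embeds the
trajectory.
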