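# tilelink

Linking regulatory chromatin to gene expression in single-cell multi-ome data.

Joint scATAC-seq + scRNA-seq ("multi-ome") assays measure chromatin
accessibility and gene expression in the same cells. `tilelink` models, for
each gene, the single-cell expression as a function of the Tn5 insertion
counts in non-overlapping 500 bp tiles spanning the gene body and 250 kb of
flanking sequence, and uses the fitted model to call cell-type-specific
candidate enhancers, test their enrichment for fine-mapped GWAS/eQTL and
curated regulatory variants against a matched background, and trace
differentiation as a chromatin-potential vector field. It is written for
computational genomicists analysing 10x-style multi-ome experiments or
benchmarking enhancer–gene linking methods on synthetic data.

## The model

For gene *g* with cell × tile accessibility matrix *X* (ReadsInTSS-normalised,
then min–max scaled per tile on the training cells) and normalised expression
*y*, `tilelink` fits a regularized Poisson regression with non-negative
coefficients by minimising

```
L(w, ε) = (1/N) Σᵢ ( exp(Xᵢw + ε) − yᵢ (Xᵢw + ε) ) + α ‖w‖₂²,   w ≥ 0
```

with projected Adam. Non-negativity restricts the model to positive
regulators, so tiles with large coefficients are candidate enhancers. The L2
weight α is chosen by four-fold cross-validation on held-out Poisson
deviance; generalisation is the Spearman ρ between predicted and observed
expression on a 25% test split. Downstream:

- **Shapley attribution** — for the linear predictor, the Shapley value of
  tile *t* for a profile *x* is `w_t (x_t − mean(X_·t))`; cell-type scores
  average 500 draws of 50-cell pseudobulks and are z-scored across tiles.
- **Tile significance** — a paired one-sided Wilcoxon signed-rank test on
  held-out cells compares absolute prediction errors with and without
  (coefficient zeroed) each tile, BH-corrected across the run.
- **Gene-linked tiles** — tiles with model ρ > 0.1, Shapley z > 0.5 and
  FDR < 0.001.
- **Variant enrichment** — precision/probability ratios within groups matched
  on MAF bin (<0.01, 0.01–0.1, >0.1), LD block and distance class
  (gene body / promoter-proximal / downstream / distal), averaged over groups
  and traits or genes, with a 1,000-iteration bootstrap CI.
- **Chromatin potential** — arrows from each cell toward the cells whose
  smoothed observed expression best matches its smoothed predicted
  expression (top-10 by Pearson correlation), drawn on a 2D layout and
  grid-averaged.

A seeded synthetic-data module generates multi-ome bundles with planted
enhancer→gene effects, variant universes with controlled enrichment, and
lead–lag differentiation trajectories, so the full pipeline is testable
without external downloads.

## Worked example

```python
import numpy as np
from tilelink import SimulationSpec, simulate_multiome
from tilelink.pipeline import fit_gene

ds = simulate_multiome(SimulationSpec(n_cells=2000, n_genes=1, seed=1))
results, X = fit_gene(ds, "gene_0", seed=1)
print(results.summary())
print("planted enhancer tiles:", ds.truth["gene_0"]["active_tiles"])
print("recovered tiles:       ", results.recovered_tiles())
```

prints

```
Tile-accessibility Poisson regression: gene_0
========================================================
n tiles:              200
n train / test cells: 1500 / 500
alpha (L2, CV):       0.01
intercept:            3.1546
nonzero coefficients: 97
max coefficient:      1.8117
test Spearman rho:    0.8236
converged:            True (490 iterations)
CV deviance by alpha: 0.01: -709.7374, 0.1: -709.6910, 1: -708.3912, 10: -681.0692, 100: -636.9037
planted enhancer tiles: [ 43 112 137 154 164]
recovered tiles:        [ 43 112 137 154 164]
```

The five tiles carrying the planted regulatory effect are exactly the five
with dominant coefficients, and the model explains held-out expression with
ρ ≈ 0.82. From here, `tilelink.pipeline.run_linking` adds Shapley scores,
tile significance and the gene-linked-tile calls, and
`tilelink.pipeline.trajectory_potential` computes a chromatin-potential
field on a simulated differentiation trajectory.

A CLI mirrors the workflow on files:
`tilelink simulate | prepare | train | shapley | enrich | potential`
(see `tilelink --help`).

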