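"""End-to-end workflows combining the building blocks.

These functions wire the simulator (or equivalently structured real data)
through model fitting, attribution and downstream analyses, and are what the
CLI subcommands call.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .interpret import add_fdr, linked_tiles, shapley_scores, tile_significance
from .model import TileExpressionModel
from .potential import (
    PotentialField,
    filter_genes_by_correlation,
    grid_smooth,
    knn_smooth,
    lsi_embedding,
    minmax_scale_genes,
    potential_vectors,
)
from .preprocess import normalize_accessibility, normalize_expression
from .simulate import MultiomeDataset, simulate_trajectory

__all__ = ["fit_gene", "run_linking", "trajectory_potential"]


def fit_gene(dataset: MultiomeDataset, gene_id: str, seed: int = 0, **fit_kwargs):
    """Fit one gene's model from a multiome bundle; returns (results, X_normalized)."""
    model = TileExpressionModel.from_dataset(dataset, gene_id, seed=seed)
    res = model.fit(**fit_kwargs)
    X = normalize_accessibility(dataset.atac[gene_id].counts, dataset.cells["reads_in_tss"])
    if sp.issparse(X):
        X = np.asarray(X.todense())
    return res, X


def run_linking(
    dataset: MultiomeDataset,
    gene_ids=None,
    seed: int = 0,
    min_corr: float = 0.1,
    min_z: float = 0.5,
    max_q: float = 1e-3,
    shapley_iters: int = 500,
    **fit_kwargs,
):
    """Fit models, score tiles and call gene-linked tiles for a dataset.

    Returns a dict with per-gene results, Shapley tables, the pooled
    significance frame (BH-corrected across the whole run) and the
    linked-tiles frame.
    """
    gene_ids = list(gene_ids if gene_ids is not None else dataset.gene_ids)
    cell_types = dataset.cells["cell_type"].to_numpy()
    results, tables, sigs = {}, [], []
    for gene_id in gene_ids:
        res, X = fit_gene(dataset, gene_id, seed=seed, **fit_kwargs)
        results[gene_id] = res
        tr, te = res.split.train_idx, res.split.test_idx
        Xs_tr = res.scaler.transform(X[tr])
        Xs_te = res.scaler.transform(X[te])
        tables.extend(
            shapley_scores(res, Xs_tr, cell_types[tr], seed=seed, n_iter=shapley_iters).values()
        )
        y = res.model.y
        sigs.append(tile_significance(res, Xs_te, y[te], cell_types[te]))
    sig = add_fdr(pd.concat(sigs, ignore_index=True))
    linked = linked_tiles(tables, sig, results, min_corr=min_corr, min_z=min_z, max_q=max_q)
    return {"results": results, "shapley": tables, "significance": sig, "linked": linked}


def trajectory_potential(
    seed: int = 0,
    delta: float = 0.15,
    k_smooth: int = 50,
    k_target: int = 10,
    grid_size: int = 30,
    alpha: float = 0.1,
    n_cells: int = 400,
    n_genes: int = 30,
    traj=None,
):
    """Chromatin potential on a (simulated) lead-lag trajectory.

    Fits one model per gene with a fixed L2 weight, predicts expression for
    every cell, smooths predicted and observed expression over the scATAC LSI
    kNN graph, filters to positively correlated genes, min-max scales, and
    computes arrows and their grid average. Returns (field, grid triple,
    per-cell cosine similarity against the true trajectory direction).
    """
    if traj is None:
        traj = simulate_trajectory(n_cells=n_cells, n_genes=n_genes, delta=delta, seed=seed)
    n = len(traj.pseudotime)
    obs = np.asarray(normalize_expression(traj.rna))
    pred = np.zeros_like(obs)
    for g, gene_id in enumerate(traj.gene_ids):
        X = normalize_accessibility(traj.atac[gene_id], traj.reads_in_tss)
        if sp.issparse(X):
            X = np.asarray(X.todense())
        model = TileExpressionModel(obs[:, g], X, gene_id=gene_id, seed=seed)
        res = model.fit(alpha=alpha)
        pred[:, g] = res.predict(X)

    emb = lsi_embedding(sp.hstack([traj.atac[g] for g in traj.gene_ids]),
                        n_dims=min(10, n - 1), seed=seed)
    pred_s = knn_smooth(pred, emb, k=k_smooth)
    obs_s = knn_smooth(obs, emb, k=k_smooth)
    keep = filter_genes_by_correlation(pred_s, obs_s)
    pred_s, obs_s = pred_s[:, keep], obs_s[:, keep]
    field = potential_vectors(
        minmax_scale_genes(pred_s), minmax_scale_genes(obs_s), traj.layout,
        k_target=k_target, genes_used=np.asarray(traj.gene_ids)[keep],
    )
    grid = grid_smooth(field, grid_size=grid_size)

    # true forward direction: tangent of the layout curve (x, 0.5 sin(pi x))
    t = traj.pseudotime
    true_dir = np.column_stack([np.ones(n), 0.5 * np.pi * np.cos(np.pi * t)])
    na = np.linalg.norm(field.arrows, axis=1)
    nt = np.linalg.norm(true_dir, axis=1)
    ok = na > 0
    cos = np.full(n, np.nan)
    cos[ok] = np.sum(field.arrows[ok] * true_dir[ok], axis=1) / (na[ok] * nt[ok])
    return field, grid, cos
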