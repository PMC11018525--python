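"""Cell-type-specific tile attribution and significance.

For a fitted linear-link model the approximate Shapley value of tile t for a
profile x is w_t (x_t - mean(X_{*,t})), the coefficient times the deviation
of the profile's accessibility from the training background. Cell-type
scores average this over repeated 50-cell pseudobulk draws; a per-gene,
per-cell-type z-score across tiles flags candidate enhancers. Tile
significance asks, on held-out cells, whether removing a tile's contribution
(zeroing w_t) worsens the prediction, via a one-sided paired Wilcoxon
signed-rank test on absolute prediction errors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import bh_fdr, dependent_correlation_test, mann_whitney, paired_signed_rank

__all__ = [
    "ShapleyTable",
    "shapley_scores",
    "tile_significance",
    "linked_tiles",
    "correlation_comparison",
    "interaction_score_comparison",
]

logger = logging.getLogger(__name__)

MIN_CELLS_PER_TYPE = 100
PSEUDOBULK_SIZE = 50
PSEUDOBULK_ITERS = 500


@dataclass
class ShapleyTable:
    """Mean approximate Shapley value and z-score per tile for one cell type."""

    gene_id: str | None
    cell_type: str
    values: np.ndarray  # per-tile mean Shapley value over pseudobulk draws
    z: np.ndarray  # standardized across tiles within (gene, cell type)
    n_cells_in_type: int
    n_pseudobulk_iters: int
    pseudobulk_size: int


def shapley_profile(coef: np.ndarray, profile: np.ndarray, background_mean: np.ndarray):
    """shap_t = w_t (x_t - mean_t) for a single (pseudobulk) profile."""
    return coef * (profile - background_mean)


def shapley_scores(
    results,
    X_train_scaled,
    cell_types,
    seed: int = 0,
    n_iter: int = PSEUDOBULK_ITERS,
    pseudobulk_size: int = PSEUDOBULK_SIZE,
    min_cells: int = MIN_CELLS_PER_TYPE,
) -> dict[str, ShapleyTable]:
    """Cell-type-specific approximate Shapley scores for a fitted gene model.

    Per iteration, ``pseudobulk_size`` training cells of the type are sampled
    without replacement and averaged into a pseudobulk profile; its Shapley
    values are coef * (profile - background mean over *all* training cells).
    Values are averaged over ``n_iter`` iterations and z-scored across tiles.
    Cell types with fewer than ``min_cells`` cells are skipped.
    """
    X = np.asarray(X_train_scaled, dtype=float)
    cell_types = np.asarray(cell_types)
    if X.shape[0] != len(cell_types):
        raise ValueError("cell_types must label the training rows of X")
    background = X.mean(axis=0)
    rng = np.random.default_rng(seed)
    out: dict[str, ShapleyTable] = {}
    for ct in pd.unique(cell_types):
        rows = np.flatnonzero(cell_types == ct)
        if len(rows) < min_cells:
            logger.info("skipping cell type %s: %d < %d cells", ct, len(rows), min_cells)
            continue
        acc = np.zeros(X.shape[1])
        size = min(pseudobulk_size, len(rows))
        for _ in range(n_iter):
            draw = rng.choice(rows, size=size, replace=False)
            acc += X[draw].mean(axis=0)
        mean_profile = acc / n_iter
        values = shapley_profile(results.coef, mean_profile, background)
        sd = values.std()
        z = (values - values.mean()) / sd if sd > 0 else np.zeros_like(values)
        out[str(ct)] = ShapleyTable(
            gene_id=results.gene_id,
            cell_type=str(ct),
            values=values,
            z=z,
            n_cells_in_type=len(rows),
            n_pseudobulk_iters=n_iter,
            pseudobulk_size=size,
        )
    return out


def tile_significance(
    results,
    X_test_scaled,
    y_test,
    cell_types,
    tiles=None,
) -> pd.DataFrame:
    """Per-(tile, cell type) significance of a tile's contribution on test cells.

    "Without tile t" zeroes the coefficient w_t, leaving the scaler and
    intercept untouched; the paired one-sided Wilcoxon signed-rank test asks
    whether |yhat_without - y| exceeds |yhat_with - y|. Tiles with w_t = 0
    give identical predictions and p = 1 by convention. Returns a tidy frame
    with columns gene_id, cell_type, tile, p; BH correction across the whole
    run is the caller's job (see :func:`add_fdr`).
    """
    X = np.asarray(X_test_scaled, dtype=float)
    y = np.asarray(y_test, dtype=float)
    cell_types = np.asarray(cell_types)
    if tiles is None:
        tiles = np.arange(results.n_tiles)
    eta = X @ results.coef + results.intercept
    yhat = np.exp(eta)
    rows = []
    for ct in pd.unique(cell_types):
        mask = cell_types == ct
        err_with = np.abs(yhat[mask] - y[mask])
        for t in tiles:
            wt = results.coef[t]
            if wt == 0:
                p = 1.0
            else:
                yhat_wo = np.exp(eta[mask] - X[mask, t] * wt)
                err_without = np.abs(yhat_wo - y[mask])
                p = paired_signed_rank(err_without, err_with, alternative="greater")
            rows.append((results.gene_id, str(ct), int(t), p))
    return pd.DataFrame(rows, columns=["gene_id", "cell_type", "tile", "p"])


def add_fdr(sig: pd.DataFrame) -> pd.DataFrame:
    """BH-adjust p across every (gene, tile, cell type) test in the run."""
    sig = sig.copy()
    sig["q"] = bh_fdr(sig["p"].to_numpy())
    return sig


def linked_tiles(
    shapley: dict[str, ShapleyTable] | list[ShapleyTable],
    sig: pd.DataFrame,
    results_by_gene,
    min_corr: float = 0.1,
    min_z: float = 0.5,
    max_q: float = 1e-3,
) -> pd.DataFrame:
    """Gene-linked tiles: test rho > min_corr, Shapley z > min_z and FDR < max_q.

    ``shapley`` may cover several genes (list) or one (dict keyed by cell
    type); ``results_by_gene`` maps gene_id -> fitted results. The output is
    ranked by significance p within (gene, cell type) for enrichment-recall
    use, with columns gene_id, cell_type, tile, z, p, q.
    """
    tables = list(shapley.values()) if isinstance(shapley, dict) else list(shapley)
    if "q" not in sig.columns:
        sig = add_fdr(sig)
    frames = []
    for tab in tables:
        res = results_by_gene[tab.gene_id]
        if not (res.test_spearman > min_corr):
            continue
        zpass = np.flatnonzero(tab.z > min_z)
        if len(zpass) == 0:
            continue
        sub = sig[(sig["gene_id"] == tab.gene_id) & (sig["cell_type"] == tab.cell_type)]
        sub = sub[sub["tile"].isin(zpass) & (sub["q"] < max_q)]
        if len(sub) == 0:
            continue
        sub = sub.copy()
        sub["z"] = tab.z[sub["tile"].to_numpy()]
        frames.append(sub)
    if not frames:
        return pd.DataFrame(columns=["gene_id", "cell_type", "tile", "p", "q", "z"])
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["p", "q"], kind="mergesort").reset_index(drop=True)


def correlation_comparison(pred_a, pred_b, observed) -> dict:
    """Compare two predictors of the same observed expression on shared cells.

    rho12 = corr(pred_a, obs), rho13 = corr(pred_b, obs), rho23 = corr(pred_a,
    pred_b); the one-sided dependent-correlation t-test asks whether predictor
    a correlates better with the observations than predictor b.
    """
    from scipy.stats import spearmanr

    n = len(observed)
    rho12 = float(spearmanr(pred_a, observed).statistic)
    rho13 = float(spearmanr(pred_b, observed).statistic)
    rho23 = float(spearmanr(pred_a, pred_b).statistic)
    t, p = dependent_correlation_test(rho12, rho13, rho23, n)
    return {"rho12": rho12, "rho13": rho13, "rho23": rho23, "n": n, "t": t, "p": p}


def interaction_score_comparison(
    shapley_values: np.ndarray,
    interactions: list[np.ndarray],
    accessibility: np.ndarray,
    reference_accessibility=None,
    seed: int = 0,
    n_bins: int = 10,
    min_accessibility_quantile: float = 0.10,
):
    """Do tiles with chromatin interactions carry higher Shapley scores?

    interactions: per-interaction arrays of spanned tile indices; the score of
    an interaction is the max Shapley value across its tiles. Background =
    tiles not in any interaction. Both sets are filtered to accessibility
    above the ``min_accessibility_quantile`` of ``reference_accessibility``
    (default: the tile accessibilities themselves), then subsampled within
    accessibility quantile bins so the two distributions match, and compared
    with a one-sided Mann-Whitney U test (interacting > background).

    Returns (p, n_interacting, n_background) or None if a matched set is empty.
    """
    shapley_values = np.asarray(shapley_values, dtype=float)
    accessibility = np.asarray(accessibility, dtype=float)
    ref = accessibility if reference_accessibility is None else np.asarray(reference_accessibility)
    floor = np.quantile(ref, min_accessibility_quantile)

    in_tiles = np.unique(np.concatenate([np.asarray(i) for i in interactions])) if interactions else np.array([], int)
    fg_scores, fg_acc = [], []
    for tiles in interactions:
        tiles = np.asarray(tiles)
        ok = accessibility[tiles] > floor
        if ok.any():
            fg_scores.append(shapley_values[tiles].max())
            fg_acc.append(accessibility[tiles].max())
    fg_scores = np.asarray(fg_scores)
    fg_acc = np.asarray(fg_acc)
    bg_mask = np.ones(len(shapley_values), dtype=bool)
    bg_mask[in_tiles] = False
    bg_mask &= accessibility > floor
    bg_scores = shapley_values[bg_mask]
    bg_acc = accessibility[bg_mask]
    if len(fg_scores) == 0 or len(bg_scores) == 0:
        logger.info("interaction comparison skipped: empty foreground or background")
        return None

    # quantile-bin subsampling to match accessibility distributions
    edges = np.quantile(np.concatenate([fg_acc, bg_acc]), np.linspace(0, 1, n_bins + 1))
    edges[-1] += 1e-9
    rng = np.random.default_rng(seed)
    fg_keep, bg_keep = [], []
    fg_bin = np.clip(np.searchsorted(edges, fg_acc, side="right") - 1, 0, n_bins - 1)
    bg_bin = np.clip(np.searchsorted(edges, bg_acc, side="right") - 1, 0, n_bins - 1)
    for b in range(n_bins):
        f = np.flatnonzero(fg_bin == b)
        g = np.flatnonzero(bg_bin == b)
        k = min(len(f), len(g))
        if k == 0:
            continue
        fg_keep.append(rng.choice(f, size=k, replace=False))
        bg_keep.append(rng.choice(g, size=k, replace=False))
    if not fg_keep or not bg_keep:
        logger.info("interaction comparison skipped: empty matched set")
        return None
    fg_m = fg_scores[np.concatenate(fg_keep)]
    bg_m = bg_scores[np.concatenate(bg_keep)]
    p = mann_whitney(fg_m, bg_m, alternative="greater")
    return p, len(fg_m), len(bg_m)
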