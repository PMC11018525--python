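"""Normalisation, gene selection, feature scaling, cell splitting, downsampling.

Expression is normalised to counts per ``scale`` (default 10,000) per cell;
tile accessibility is normalised by each cell's reads-in-TSS and rescaled by
the cohort median so magnitudes stay comparable across datasets (the median
factor cancels under the subsequent per-tile min-max scaling).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

__all__ = [
    "SplitSpec",
    "TileScaler",
    "normalize_expression",
    "normalize_accessibility",
    "select_variable_genes",
    "sparsity_filter",
    "split_cells",
    "downsample_counts",
    "downsample_cells",
]


def _row_scale(mat, factors):
    """Multiply row i of a dense/sparse matrix by factors[i]."""
    if sp.issparse(mat):
        return sp.diags(factors) @ mat.tocsr()
    return np.asarray(mat, dtype=float) * factors[:, None]


def normalize_expression(raw_counts, scale: float = 10_000.0, include=None):
    """Counts-per-``scale`` normalisation of a cell x gene count matrix.

    include: optional boolean mask of cells that must have nonzero totals;
    cells outside the mask are passed through as zeros.
    """
    raw = raw_counts.tocsr() if sp.issparse(raw_counts) else np.asarray(raw_counts, dtype=float)
    totals = np.asarray(raw.sum(axis=1)).ravel()
    if include is None:
        include = np.ones(raw.shape[0], dtype=bool)
    zero = include & (totals == 0)
    if zero.any():
        raise ValueError(f"cell {int(np.flatnonzero(zero)[0])} has zero total counts")
    factors = np.zeros_like(totals, dtype=float)
    factors[totals > 0] = scale / totals[totals > 0]
    return _row_scale(raw, factors)


def normalize_accessibility(counts, reads_in_tss):
    """Depth-normalise tile counts: x[c,t] = counts[c,t] / tss[c] * median(tss)."""
    tss = np.asarray(reads_in_tss, dtype=float)
    if (tss <= 0).any():
        raise ValueError("reads_in_tss must be positive")
    factors = np.median(tss) / tss
    return _row_scale(counts, factors)


def select_variable_genes(raw_counts, gene_ids, n: int = 5000, scale: float = 10_000.0):
    """Top-n genes by dispersion (variance/mean) of log1p-normalised expression.

    Constant (zero-variance) genes are never selected; ties break
    lexicographically on gene_id so the selection is deterministic.
    """
    raw = raw_counts.tocsc() if sp.issparse(raw_counts) else np.asarray(raw_counts)
    norm = normalize_expression(raw_counts, scale=scale)
    if sp.issparse(norm):
        norm = np.asarray(norm.todense())
    logged = np.log1p(norm)
    mean = logged.mean(axis=0)
    var = logged.var(axis=0)
    dispersion = np.where(mean > 0, var / np.where(mean > 0, mean, 1.0), 0.0)
    gene_ids = np.asarray(gene_ids)
    # genes constant in raw counts carry no signal even if depth normalisation
    # spreads their normalised values
    if sp.issparse(raw):
        raw_dense = np.asarray(raw.todense())
    else:
        raw_dense = raw
    eligible = (var > 0) & (raw_dense.var(axis=0) > 0)
    # sort by (-dispersion, gene_id): lexsort uses the last key as primary
    order = np.lexsort((gene_ids, -dispersion))
    order = order[eligible[order]]
    return gene_ids[order[: min(n, len(order))]].tolist()


def sparsity_filter(raw_counts, gene_ids, max_zero_fraction: float = 0.9):
    """Drop genes whose expression is zero in more than max_zero_fraction of cells."""
    raw = raw_counts.tocsc() if sp.issparse(raw_counts) else np.asarray(raw_counts)
    n_cells = raw.shape[0]
    if sp.issparse(raw):
        nonzero = raw.getnnz(axis=0)
    else:
        nonzero = (raw != 0).sum(axis=0)
    zero_frac = 1.0 - nonzero / n_cells
    gene_ids = np.asarray(gene_ids)
    return gene_ids[zero_frac <= max_zero_fraction].tolist()


class TileScaler:
    """Per-tile min-max scaler fitted on training cells only.

    The learned affine rule is applied unchanged to held-out cells, so test
    values may fall outside [0, 1] (no clipping). Constant tiles map to 0.
    """

    def __init__(self):
        self.min_ = None
        self.max_ = None

    def fit(self, x_train) -> "TileScaler":
        x = np.asarray(x_train.todense()) if sp.issparse(x_train) else np.asarray(x_train, float)
        self.min_ = x.min(axis=0)
        self.max_ = x.max(axis=0)
        return self

    def transform(self, x) -> np.ndarray:
        if self.min_ is None:
            raise RuntimeError("TileScaler must be fitted before transform")
        x = np.asarray(x.todense()) if sp.issparse(x) else np.asarray(x, float)
        span = self.max_ - self.min_
        safe = np.where(span > 0, span, 1.0)
        out = (x - self.min_) / safe
        out[:, span == 0] = 0.0
        return out

    def fit_transform(self, x) -> np.ndarray:
        return self.fit(x).transform(x)


@dataclass
class SplitSpec:
    """Train/test cell split with a k-fold partition of the training cells."""

    train_idx: np.ndarray
    test_idx: np.ndarray
    fold_ids: np.ndarray | None  # per-train-cell fold label in 0..k-1
    seed: int

    @property
    def k_folds(self) -> int:
        return int(self.fold_ids.max()) + 1 if self.fold_ids is not None else 0

    def fold(self, j: int) -> tuple[np.ndarray, np.ndarray]:
        """(fit indices, held-out indices) for CV fold j, as cell indices."""
        held = self.fold_ids == j
        return self.train_idx[~held], self.train_idx[held]


def split_cells(n: int, test_fraction: float = 0.25, k_folds: int = 4, seed: int = 0) -> SplitSpec:
    """Seeded uniform split into test cells and k balanced CV folds of the rest."""
    if n < 2 * k_folds:
        raise ValueError(f"need at least {2 * k_folds} cells to split, got {n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_test = int(round(n * test_fraction))
    test_idx = np.sort(perm[:n_test])
    train_idx = np.sort(perm[n_test:])
    fold_ids = rng.permutation(np.arange(len(train_idx)) % k_folds)
    return SplitSpec(train_idx=train_idx, test_idx=test_idx, fold_ids=fold_ids, seed=seed)


def downsample_counts(matrix, fraction: float, seed: int = 0):
    """Binomially thin each count so expected totals are fraction x original.

    Every entry k becomes Binomial(k, fraction); entries can only shrink and
    zeros stay zero. fraction = 1 is the identity.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if fraction == 1:
        return matrix.copy()
    rng = np.random.default_rng(seed)
    if sp.issparse(matrix):
        out = matrix.tocsr(copy=True)
        out.data = rng.binomial(out.data.astype(np.int64), fraction)
        out.eliminate_zeros()
        return out
    return rng.binomial(np.asarray(matrix, dtype=np.int64), fraction)


def downsample_cells(n_cells: int, fraction: float, seed: int = 0) -> np.ndarray:
    """Seeded uniform subsample of cell indices (sorted), no stratification."""
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    rng = np.random.default_rng(seed)
    k = int(round(n_cells * fraction))
    return np.sort(rng.choice(n_cells, size=k, replace=False))
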