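"""Chromatin-potential vector fields.

Accessibility changes at regulatory elements tend to precede the expression
changes of their target genes along a differentiation trajectory. A cell
whose accessibility-predicted expression looks like the *observed* expression
of cells further along the trajectory is therefore assigned an arrow pointing
toward those cells: for each cell i, find the k cells whose smoothed,
min-max-scaled observed expression correlates best with cell i's smoothed,
scaled predicted expression, and draw an arrow from i to their average 2D
layout position. Arrows are optionally averaged on a regular grid for
display.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.stats import spearmanr
from sklearn.decomposition import TruncatedSVD
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "PotentialField",
    "lsi_embedding",
    "knn_smooth",
    "filter_genes_by_correlation",
    "minmax_scale_genes",
    "potential_vectors",
    "grid_smooth",
    "cosine_compare",
]

logger = logging.getLogger(__name__)


def lsi_embedding(counts, n_dims: int = 30, seed: int = 0) -> np.ndarray:
    """Latent semantic indexing of cell x feature counts: TF-IDF + truncated SVD."""
    X = sp.csr_matrix(counts, dtype=float)
    row = np.asarray(X.sum(axis=1)).ravel()
    row[row == 0] = 1.0
    tf = sp.diags(1.0 / row) @ X
    df = np.asarray((X > 0).sum(axis=0)).ravel()
    idf = X.shape[0] / (1.0 + df)
    mat = tf @ sp.diags(idf)
    mat.data = np.log1p(mat.data * 1e4)
    max_rank = min(mat.shape) - 1
    if n_dims > max_rank:
        logger.warning("n_dims %d exceeds rank; reduced to %d", n_dims, max_rank)
        n_dims = max_rank
    svd = TruncatedSVD(n_components=n_dims, random_state=seed)
    return svd.fit_transform(mat)


def knn_smooth(expression, embedding, k: int = 50) -> np.ndarray:
    """Replace each cell's expression by the mean over its k nearest neighbours.

    Euclidean neighbours in the embedding, self included (k = 1 is the
    identity); k is clamped to the number of cells.
    """
    expr = np.asarray(expression.todense()) if sp.issparse(expression) else np.asarray(expression, float)
    emb = np.asarray(embedding, dtype=float)
    if emb.shape[0] != expr.shape[0]:
        raise ValueError("embedding and expression must have the same number of cells")
    n = expr.shape[0]
    if k > n:
        logger.warning("k=%d exceeds n_cells=%d; clamped", k, n)
        k = n
    nn = NearestNeighbors(n_neighbors=k).fit(emb)
    _, idx = nn.kneighbors(emb)
    return expr[idx].mean(axis=1)


def filter_genes_by_correlation(pred, obs) -> np.ndarray:
    """Indices of genes whose predicted and observed expression correlate positively.

    Spearman over all cells, strict rho > 0; degenerate (constant) genes drop.
    """
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    keep = []
    for g in range(pred.shape[1]):
        if np.ptp(pred[:, g]) == 0 or np.ptp(obs[:, g]) == 0:
            continue
        rho = spearmanr(pred[:, g], obs[:, g]).statistic
        if rho > 0:
            keep.append(g)
    return np.asarray(keep, dtype=int)


def minmax_scale_genes(mat) -> np.ndarray:
    """Per-gene min-max scaling over all cells (constant genes map to 0)."""
    mat = np.asarray(mat, dtype=float)
    lo = mat.min(axis=0)
    span = mat.max(axis=0) - lo
    safe = np.where(span > 0, span, 1.0)
    out = (mat - lo) / safe
    out[:, span == 0] = 0.0
    return out


@dataclass
class PotentialField:
    """Per-cell chromatin-potential arrows on a 2D layout."""

    positions: np.ndarray  # (n, 2) source positions
    arrows: np.ndarray  # (n, 2) displacement vectors
    degenerate: np.ndarray  # (n,) flag: constant expression vector, arrow forced to 0
    genes_used: np.ndarray | None = None

    @property
    def n_cells(self) -> int:
        return len(self.positions)


def potential_vectors(
    pred_scaled,
    obs_scaled,
    layout,
    k_target: int = 10,
    genes_used=None,
) -> PotentialField:
    """Arrows from each cell toward the cells whose observed expression best
    matches its predicted expression.

    The neighbour metric is the Pearson correlation between cell i's
    (smoothed, scaled) predicted vector and every cell's observed vector;
    self-matches are allowed, so stationary states get near-zero arrows.
    Cells with a constant predicted vector are flagged and get a zero arrow.
    """
    P = np.asarray(pred_scaled, dtype=float)
    O = np.asarray(obs_scaled, dtype=float)
    layout = np.asarray(layout, dtype=float)
    if P.shape != O.shape or layout.shape[0] != P.shape[0]:
        raise ValueError("pred, obs and layout must agree on the number of cells")
    n = P.shape[0]
    k = min(k_target, n)

    Pc = P - P.mean(axis=1, keepdims=True)
    Oc = O - O.mean(axis=1, keepdims=True)
    pn = np.linalg.norm(Pc, axis=1)
    on = np.linalg.norm(Oc, axis=1)
    degenerate = pn == 0
    pn_safe = np.where(degenerate, 1.0, pn)
    on_safe = np.where(on == 0, 1.0, on)
    corr = (Pc / pn_safe[:, None]) @ (Oc / on_safe[:, None]).T
    corr[:, on == 0] = -np.inf  # constant observed vectors are never targets

    arrows = np.zeros((n, 2))
    # top-k columns by correlation per row
    top = np.argpartition(-corr, kth=k - 1, axis=1)[:, :k]
    targets = layout[top].mean(axis=1)
    arrows = targets - layout
    arrows[degenerate] = 0.0
    if degenerate.any():
        logger.info("%d cells have constant predicted vectors; arrows zeroed", degenerate.sum())
    return PotentialField(
        positions=layout, arrows=arrows, degenerate=degenerate, genes_used=genes_used
    )


def grid_smooth(field: PotentialField, grid_size: int = 30):
    """Average member-cell arrows within a grid over the layout bounding box.

    Returns (grid_centers, grid_vectors, counts) for non-empty cells only.
    """
    pos = field.positions
    lo = pos.min(axis=0)
    hi = pos.max(axis=0)
    span = hi - lo
    if (span == 0).any():
        raise ValueError("layout bounding box is degenerate")
    ix = np.minimum((grid_size * (pos - lo) / span).astype(int), grid_size - 1)
    flat = ix[:, 0] * grid_size + ix[:, 1]
    centers, vectors, counts = [], [], []
    for cell_id in np.unique(flat):
        members = flat == cell_id
        gx, gy = divmod(int(cell_id), grid_size)
        centers.append(
            [lo[0] + (gx + 0.5) * span[0] / grid_size, lo[1] + (gy + 0.5) * span[1] / grid_size]
        )
        vectors.append(field.arrows[members].mean(axis=0))
        counts.append(int(members.sum()))
    return np.asarray(centers), np.asarray(vectors), np.asarray(counts)


def cosine_compare(field_a: PotentialField, field_b: PotentialField, cell_types=None):
    """Per-cell cosine similarity of two arrow fields, plus magnitude differences.

    Cells where either arrow is the zero vector get NaN cosine (flagged as
    undefined). If cell_types is given, mean magnitude difference (|a| - |b|)
    is aggregated per type. Returns (cosine array, magnitude_diff) where
    magnitude_diff is a dict when cell_types is provided, else an array.
    """
    a, b = field_a.arrows, field_b.arrows
    if a.shape != b.shape:
        raise ValueError("fields must cover the same cells")
    na = np.linalg.norm(a, axis=1)
    nb = np.linalg.norm(b, axis=1)
    ok = (na > 0) & (nb > 0)
    cos = np.full(len(a), np.nan)
    cos[ok] = np.sum(a[ok] * b[ok], axis=1) / (na[ok] * nb[ok])
    mag = na - nb
    if cell_types is not None:
        cell_types = np.asarray(cell_types)
        by_type = {str(ct): float(mag[cell_types == ct].mean()) for ct in np.unique(cell_types)}
        return cos, by_type
    return cos, mag
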