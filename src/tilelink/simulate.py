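"""Seeded synthetic multi-ome data with planted regulatory structure.

The generator emulates the generative structure the regression model assumes:
tile-level Tn5 insertion counts are Poisson with cell-type-specific base
rates scaled by a log-normal per-cell depth factor, and a gene's RNA counts
are Poisson with rate exp(X_scaled w* + eps*) times an RNA depth factor,
where w* is a sparse non-negative coefficient vector over the gene's tiles
(the planted enhancers). Variant universes with matched MAF/LD/distance
structure and a lead-lag differentiation trajectory (accessibility switching
before expression) are generated for the enrichment and chromatin-potential
components.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import GeneAnnotation, GeneWindow, TileMatrix, make_gene_window
from .preprocess import TileScaler, normalize_accessibility

__all__ = [
    "SimulationSpec",
    "MultiomeDataset",
    "simulate_multiome",
    "simulate_variants",
    "simulate_trajectory",
    "write_fragments",
]


@dataclass
class SimulationSpec:
    """Study conditions for the synthetic multi-ome.

    Defaults give 2,000 cells, two equally sized cell types, and per gene a
    200-tile window (10 kb gene body, 45 kb flanks, 500 bp tiles) with five
    planted enhancer tiles that are preferentially accessible in the
    expressing cell type.
    """

    n_cells: int = 2000
    n_genes: int = 3
    cell_types: tuple[str, ...] = ("type_0", "type_1")
    proportions: tuple[float, ...] = (0.5, 0.5)
    gene_length: int = 10_000
    flank: int = 45_000
    tile_size: int = 500
    n_active_tiles: int = 5
    w_active_range: tuple[float, float] = (1.0, 2.0)
    epsilon: float = 0.0
    base_rate: float = 0.2  # expected insertions per cell in a background tile
    active_rate_on: float = 2.0  # enhancer tile rate in the expressing cell type
    active_rate_off: float = 0.05  # enhancer tile rate elsewhere
    depth_sigma: float = 0.35  # log-normal sd of per-cell ATAC depth factors
    rna_depth_sigma: float = 0.35
    n_background_genes: int = 50  # unmodelled genes stabilising per-cell RNA totals
    overdispersion: float = 0.0  # gamma-Poisson mixing; 0 = pure Poisson
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.proportions) - 1.0) > 1e-9:
            raise ValueError("cell-type proportions must sum to 1")
        if len(self.proportions) != len(self.cell_types):
            raise ValueError("one proportion per cell type")
        if min(self.base_rate, self.active_rate_on, self.active_rate_off) < 0:
            raise ValueError("rates must be non-negative")


@dataclass
class MultiomeDataset:
    """Bundle of matched scATAC tile matrices and scRNA counts for the same cells."""

    cells: pd.DataFrame  # barcode, cell_type, reads_in_tss
    rna: sp.csr_matrix  # cells x (modelled genes + background genes)
    gene_ids: list[str]  # modelled genes, indexing the first columns of rna
    genes: list[GeneAnnotation]
    windows: dict[str, GeneWindow]
    atac: dict[str, TileMatrix]
    truth: dict = field(default_factory=dict)

    @property
    def n_cells(self) -> int:
        return len(self.cells)


def _poisson(rng, lam, overdispersion=0.0):
    if overdispersion > 0:
        shape = 1.0 / overdispersion
        lam = rng.gamma(shape, lam * overdispersion)
    return rng.poisson(lam)


def simulate_multiome(spec: SimulationSpec) -> MultiomeDataset:
    """Generate matched tile accessibility and expression with planted enhancers."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_cells
    types = rng.choice(len(spec.cell_types), size=n, p=spec.proportions)
    type_labels = np.asarray(spec.cell_types)[types]
    depth = np.exp(rng.normal(0.0, spec.depth_sigma, size=n))
    rna_depth = np.exp(rng.normal(0.0, spec.rna_depth_sigma, size=n))
    reads_in_tss = np.maximum(np.round(depth * 500).astype(np.int64), 1)
    cells = pd.DataFrame(
        {
            "barcode": [f"CELL{i:05d}" for i in range(n)],
            "cell_type": type_labels,
            "reads_in_tss": reads_in_tss,
        }
    )

    genes, windows, atac, truth = [], {}, {}, {}
    rna_cols = []
    chrom_spacing = 10 * (spec.gene_length + 2 * spec.flank)
    for gi in range(spec.n_genes):
        gene_id = f"gene_{gi}"
        start = spec.flank + 1000 + gi * chrom_spacing
        gene = GeneAnnotation(gene_id, "chrS", start, start + spec.gene_length, "+")
        window = make_gene_window(gene, flank=spec.flank, tile_size=spec.tile_size)
        p = window.n_tiles

        active = np.sort(rng.choice(p, size=spec.n_active_tiles, replace=False))
        w_true = np.zeros(p)
        w_true[active] = rng.uniform(*spec.w_active_range, size=spec.n_active_tiles)

        rates = np.full((len(spec.cell_types), p), spec.base_rate)
        rates[:, active] = spec.active_rate_off
        rates[0, active] = spec.active_rate_on  # first cell type expresses the gene
        lam = rates[types] * depth[:, None]
        counts = sp.csr_matrix(_poisson(rng, lam, spec.overdispersion))
        tm = TileMatrix(gene_id=gene_id, counts=counts, window=window)
        # expression from the generator's own scaled view of the accessibility
        x_norm = normalize_accessibility(counts, reads_in_tss)
        x_scaled = TileScaler().fit_transform(x_norm)
        eta = x_scaled @ w_true + spec.epsilon
        y_counts = _poisson(rng, np.exp(eta) * rna_depth, spec.overdispersion)

        genes.append(gene)
        windows[gene_id] = window
        atac[gene_id] = tm
        truth[gene_id] = {"w": w_true, "epsilon": spec.epsilon, "active_tiles": active}
        rna_cols.append(y_counts)

    bg_rates = np.exp(rng.normal(0.0, 1.0, size=spec.n_background_genes))
    bg = _poisson(rng, rna_depth[:, None] * bg_rates[None, :] * 5.0, spec.overdispersion)
    rna = sp.csr_matrix(np.column_stack(rna_cols + [bg]))
    gene_ids = [g.gene_id for g in genes]
    return MultiomeDataset(
        cells=cells,
        rna=rna,
        gene_ids=gene_ids,
        genes=genes,
        windows=windows,
        atac=atac,
        truth={**truth, "depth": depth, "rna_depth": rna_depth},
    )


def write_fragments(dataset: MultiomeDataset, path) -> None:
    """Emit a 5-column fragments TSV whose insertions reproduce the tile counts.

    Per cell, every insertion implied by the tile counts is placed at a
    concrete position inside its tile; insertions are then paired into
    fragments (start = first, end = second + 1), so reading the file back and
    rebuilding tile matrices reproduces the counts exactly. An odd leftover
    insertion is paired with a throwaway position outside every gene window.
    """
    rows = []
    far_away = 1  # position on a spacer region before any window
    for gene_id in dataset.gene_ids:
        tm = dataset.atac[gene_id]
        win = tm.window
        coo = tm.counts.tocoo()
        for c in range(dataset.n_cells):
            sel = coo.row == c
            if not sel.any():
                continue
            tiles = np.repeat(coo.col[sel], coo.data[sel])
            # deterministic in-tile positions: spread within the tile
            offsets = np.arange(len(tiles)) % (win.tile_size - 1)
            pos = np.sort(win.window_start + tiles * win.tile_size + offsets)
            if len(pos) % 2:
                # pair the odd insertion with a spacer position outside all windows
                pos = np.sort(np.append(pos, far_away))
            barcode = dataset.cells["barcode"].iloc[c]
            for i in range(0, len(pos), 2):
                rows.append((win.chrom, int(pos[i]), int(pos[i + 1]) + 1, barcode, 1))
    frame = pd.DataFrame(rows, columns=["chrom", "start", "end", "barcode", "count"])
    frame.to_csv(path, sep="\t", header=False, index=False)


def simulate_variants(
    windows: dict[str, GeneWindow],
    enhancer_tiles: dict[str, np.ndarray],
    n_common_per_gene: int = 400,
    n_causal_per_gene: int = 40,
    enrichment_factor: float = 1.0,
    n_traits: int = 10,
    ld_block_tiles: int = 50,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Plant causal and common variants over the gene windows.

    Common variants are uniform over tiles; causal variants sample tiles with
    weight ``enrichment_factor`` on the planted enhancer tiles (factor 1 makes
    the two sets exchangeable). MAF is drawn from the same three-bin mixture
    for both sets, and LD blocks tile each window in runs of
    ``ld_block_tiles`` tiles. Returns (variants, ld_blocks) frames.
    """
    rng = np.random.default_rng(seed)
    var_rows, ld_rows = [], []
    vid = 0
    for gene_id, win in windows.items():
        p = win.n_tiles
        # LD blocks tiling the window
        for b, s in enumerate(range(0, p, ld_block_tiles)):
            e = min(s + ld_block_tiles, p)
            ld_rows.append(
                (
                    win.chrom,
                    win.window_start + s * win.tile_size,
                    win.window_start + e * win.tile_size,
                    f"{gene_id}_block{b}",
                )
            )
        weights = np.ones(p)
        enh = np.asarray(enhancer_tiles.get(gene_id, []), dtype=int)
        weights[enh] = enrichment_factor
        w_causal = weights / weights.sum()

        def draw(n_var, probs, is_causal):
            nonlocal vid
            tiles = rng.choice(p, size=n_var, p=probs)
            offsets = rng.integers(0, win.tile_size, size=n_var)
            pos = win.window_start + tiles * win.tile_size + offsets
            bins = rng.choice(3, size=n_var, p=(0.3, 0.4, 0.3))
            maf = np.select(
                [bins == 0, bins == 1, bins == 2],
                [
                    rng.uniform(0.001, 0.01, n_var),
                    rng.uniform(0.01, 0.1, n_var),
                    rng.uniform(0.1, 0.5, n_var),
                ],
            )
            pip = rng.uniform(0.5, 1.0, n_var) if is_causal else rng.uniform(0.0, 0.01, n_var)
            traits = rng.integers(0, n_traits, size=n_var)
            frame = pd.DataFrame(
                {
                    "variant_id": [f"rs{vid + i}" for i in range(n_var)],
                    "chrom": win.chrom,
                    "pos": pos.astype(np.int64),
                    "maf": maf,
                    "pip": pip,
                    "trait": pd.Series(traits).map(lambda t: f"trait_{t}"),
                    "gene": gene_id,
                    "is_causal": is_causal,
                    "is_common": not is_causal,
                }
            )
            vid += n_var
            var_rows.append(frame)

        draw(n_causal_per_gene, w_causal, True)
        draw(n_common_per_gene, np.full(p, 1.0 / p), False)

    variants = (
        pd.concat(var_rows, ignore_index=True)
        if var_rows
        else pd.DataFrame(
            columns=["variant_id", "chrom", "pos", "maf", "pip", "trait", "gene", "is_causal", "is_common"]
        )
    )
    ld_blocks = pd.DataFrame(ld_rows, columns=["chrom", "start", "end", "name"])
    return variants, ld_blocks


@dataclass
class TrajectoryDataset:
    """Differentiation trajectory where accessibility leads expression by delta."""

    atac: dict[str, sp.csr_matrix]  # per-gene cell x tile counts
    rna: np.ndarray  # cells x genes counts
    gene_ids: list[str]
    pseudotime: np.ndarray
    layout: np.ndarray  # (n, 2)
    embedding: np.ndarray  # low-dimensional space for kNN smoothing
    cell_types: np.ndarray
    driver_tiles: dict[str, int]
    reads_in_tss: np.ndarray


def simulate_trajectory(
    n_cells: int = 400,
    n_genes: int = 30,
    n_tiles_per_gene: int = 10,
    delta: float = 0.15,
    tau: float = 0.05,
    depth_sigma: float = 0.2,
    seed: int = 0,
) -> TrajectoryDataset:
    """Cells on a 1D differentiation path with a lead-lag between modalities.

    Each gene has one driver tile whose accessibility follows a sigmoid
    switching at t0; the gene's expression follows the same sigmoid shifted
    ``delta`` later in pseudotime, so accessibility anticipates expression.
    The 2D layout is a noisy curve parameterised by pseudotime.
    """
    if delta < 0:
        raise ValueError("delta must be non-negative")
    rng = np.random.default_rng(seed)
    t = np.sort(rng.uniform(0, 1, size=n_cells))
    depth = np.exp(rng.normal(0, depth_sigma, size=n_cells))
    reads_in_tss = np.maximum(np.round(depth * 500).astype(np.int64), 1)

    def sigmoid(x):
        return 1.0 / (1.0 + np.exp(-x))

    atac, driver_tiles = {}, {}
    rna = np.zeros((n_cells, n_genes), dtype=np.int64)
    gene_ids = [f"tgene_{g}" for g in range(n_genes)]
    # switch times staggered beyond both ends of the path so that at any
    # pseudotime some genes are mid-switch and profiles stay informative
    t0s = rng.uniform(-0.2, 1.0, size=n_genes)
    for g, gene_id in enumerate(gene_ids):
        driver = int(rng.integers(0, n_tiles_per_gene))
        driver_tiles[gene_id] = driver
        rates = np.full((n_cells, n_tiles_per_gene), 0.3)
        rates[:, driver] = 0.2 + 4.0 * sigmoid((t - t0s[g]) / tau)
        counts = rng.poisson(rates * depth[:, None])
        atac[gene_id] = sp.csr_matrix(counts)
        # log-linear in the (lagged) regulatory state, matching the model family
        expr_rate = np.exp(0.3 + 2.5 * sigmoid((t - t0s[g] - delta) / tau))
        rna[:, g] = rng.poisson(expr_rate * depth)

    layout = np.column_stack([t, np.sin(np.pi * t) * 0.5]) + rng.normal(0, 0.01, (n_cells, 2))
    embedding = np.column_stack([t, rng.normal(0, 0.02, size=n_cells)])
    cell_types = np.asarray(["early", "mid", "late"])[np.minimum((t * 3).astype(int), 2)]
    return TrajectoryDataset(
        atac=atac,
        rna=rna,
        gene_ids=gene_ids,
        pseudotime=t,
        layout=layout,
        embedding=embedding,
        cell_types=cell_types,
        driver_tiles=driver_tiles,
        reads_in_tss=reads_in_tss,
    )
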