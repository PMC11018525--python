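"""Readers/writers for the external formats and per-gene tile-window construction.

Coordinates are 0-based half-open throughout. Fragment files follow the
standard 5-column scATAC dialect (chrom, start, end, barcode, count); each
fragment contributes two Tn5 insertion events, at ``start`` and ``end - 1``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import h5py
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "GeneAnnotation",
    "GeneWindow",
    "TileMatrix",
    "make_gene_window",
    "read_gene_annotations",
    "read_bed",
    "read_cell_table",
    "read_fragments",
    "read_mtx",
    "write_mtx",
    "build_tile_matrix",
    "compute_reads_in_tss",
    "ModelStore",
]

DEFAULT_FLANK = 250_000
DEFAULT_TILE_SIZE = 500


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene body on the genome with the strand used for promoter labelling."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(
                f"gene {self.gene_id}: end ({self.end}) must exceed start ({self.start})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneWindow:
    """Tiling of the region spanning ``flank`` bp up/downstream of a gene body.

    Tiles are anchored at ``gene start - flank`` (window-relative, not on a
    genome-wide grid), non-overlapping, contiguous and each exactly
    ``tile_size`` bp wide.
    """

    gene_id: str
    chrom: str
    window_start: int
    tile_size: int
    n_tiles: int
    flank: int
    strand: str

    @property
    def window_end(self) -> int:
        return self.window_start + self.n_tiles * self.tile_size

    @property
    def flank_tiles(self) -> int:
        return self.flank // self.tile_size

    def tile_coords(self) -> np.ndarray:
        """(n_tiles, 2) array of half-open genomic [start, end) intervals."""
        starts = self.window_start + np.arange(self.n_tiles) * self.tile_size
        return np.column_stack([starts, starts + self.tile_size])

    def tile_of(self, pos: np.ndarray) -> np.ndarray:
        """Tile index containing each position; -1 if outside the window."""
        pos = np.asarray(pos)
        idx = (pos - self.window_start) // self.tile_size
        out = np.where((pos >= self.window_start) & (pos < self.window_end), idx, -1)
        return out.astype(np.int64)


def make_gene_window(
    gene: GeneAnnotation,
    flank: int = DEFAULT_FLANK,
    tile_size: int = DEFAULT_TILE_SIZE,
) -> GeneWindow:
    """Tile the gene body plus symmetric flanks into fixed-width bins.

    n_tiles = 2*flank/tile_size + ceil(gene_length/tile_size); e.g. an
    11,703 bp gene with 250 kb flanks and 500 bp tiles yields 1,024 tiles.
    """
    if flank <= 0 or tile_size <= 0:
        raise ValueError("flank and tile_size must be positive")
    if flank % tile_size != 0:
        raise ValueError(f"flank ({flank}) must be divisible by tile_size ({tile_size})")
    n_tiles = 2 * (flank // tile_size) + math.ceil(gene.length / tile_size)
    return GeneWindow(
        gene_id=gene.gene_id,
        chrom=gene.chrom,
        window_start=gene.start - flank,
        tile_size=tile_size,
        n_tiles=n_tiles,
        flank=flank,
        strand=gene.strand,
    )


@dataclass
class TileMatrix:
    """Sparse cell x tile Tn5 insertion counts for one gene window."""

    gene_id: str
    counts: sp.csr_matrix
    window: GeneWindow
    normalized: sp.csr_matrix | None = None

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_tiles(self) -> int:
        return self.counts.shape[1]


def read_gene_annotations(path) -> list[GeneAnnotation]:
    """Gene annotation TSV with columns gene_id, chrom, start, end, strand."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = ["gene_id", "chrom", "start", "end", "strand"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"gene annotation file missing columns: {missing}")
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"duplicate gene_id in annotation: {dup}")
    return [
        GeneAnnotation(r.gene_id, r.chrom, int(r.start), int(r.end), r.strand)
        for r in df.itertuples()
    ]


def read_bed(path) -> pd.DataFrame:
    """Minimal BED reader: chrom, start, end (+ optional name in column 4)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    df = df.rename(columns={0: "chrom", 1: "start", 2: "end", 3: "name"})
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return df


def read_cell_table(path) -> pd.DataFrame:
    """Cell metadata TSV with at least barcode and cell_type columns."""
    df = pd.read_csv(path, sep="\t")
    if "barcode" not in df.columns or "cell_type" not in df.columns:
        raise ValueError("cell table needs 'barcode' and 'cell_type' columns")
    if df["barcode"].duplicated().any():
        raise ValueError("duplicate barcodes in cell table")
    if "reads_in_tss" in df.columns and (df["reads_in_tss"] <= 0).any():
        raise ValueError("reads_in_tss must be positive for all included cells")
    return df.reset_index(drop=True)


def read_fragments(path, cells: pd.DataFrame) -> pd.DataFrame:
    """Read a 5-column fragments TSV into per-cell Tn5 insertion events.

    Each fragment with count k yields k insertions at ``start`` and k at
    ``end - 1``. Fragments whose barcode is absent from ``cells`` are skipped.

    Returns a DataFrame with columns chrom (str), pos (int), cell (int row
    index into ``cells``).
    """
    frags = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["chrom", "start", "end", "barcode", "count"],
        dtype={"chrom": str, "barcode": str},
    )
    if frags[["start", "end", "barcode"]].isna().any().any():
        bad = int(frags[["start", "end", "barcode"]].isna().any(axis=1).idxmax()) + 1
        raise ValueError(f"malformed fragment line {bad} in {path}: expected 5 columns")
    if frags["count"].isna().any():
        frags["count"] = frags["count"].fillna(1)
    frags["start"] = frags["start"].astype(np.int64)
    frags["end"] = frags["end"].astype(np.int64)
    if (frags["end"] <= frags["start"]).any():
        bad = int((frags["end"] <= frags["start"]).idxmax()) + 1
        raise ValueError(f"malformed fragment line {bad} in {path}: end must exceed start")

    barcode_to_idx = pd.Series(np.arange(len(cells)), index=cells["barcode"])
    cell_idx = frags["barcode"].map(barcode_to_idx)
    known = cell_idx.notna()
    frags = frags[known]
    cell_idx = cell_idx[known].astype(np.int64)

    count = frags["count"].to_numpy(np.int64)
    cell = np.repeat(cell_idx.to_numpy(), count)
    chrom = np.repeat(frags["chrom"].to_numpy(), count)
    start = np.repeat(frags["start"].to_numpy(), count)
    end = np.repeat(frags["end"].to_numpy(), count)
    return pd.DataFrame(
        {
            "chrom": np.concatenate([chrom, chrom]),
            "pos": np.concatenate([start, end - 1]),
            "cell": np.concatenate([cell, cell]),
        }
    )


def _merge_intervals(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sort and merge possibly-overlapping half-open intervals."""
    if len(starts) == 0:
        return starts, ends
    order = np.argsort(starts)
    starts, ends = starts[order], ends[order]
    merged_s, merged_e = [starts[0]], [ends[0]]
    for s, e in zip(starts[1:], ends[1:]):
        if s <= merged_e[-1]:
            merged_e[-1] = max(merged_e[-1], e)
        else:
            merged_s.append(s)
            merged_e.append(e)
    return np.asarray(merged_s), np.asarray(merged_e)


def _in_intervals(pos: np.ndarray, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    """Membership of positions in merged sorted half-open intervals."""
    if len(starts) == 0:
        return np.zeros(len(pos), dtype=bool)
    i = np.searchsorted(starts, pos, side="right") - 1
    ok = i >= 0
    out = np.zeros(len(pos), dtype=bool)
    out[ok] = pos[ok] < ends[i[ok]]
    return out


def build_tile_matrix(
    insertions: pd.DataFrame,
    window: GeneWindow,
    blacklist: pd.DataFrame | None = None,
    n_cells: int | None = None,
) -> TileMatrix:
    """Count Tn5 insertions per (cell, tile) within a gene window.

    Insertions outside the window are ignored. Tiles overlapping a blacklist
    interval by >= 1 bp are forced to zero.
    """
    if n_cells is None:
        n_cells = int(insertions["cell"].max()) + 1 if len(insertions) else 0
    on_chrom = insertions[insertions["chrom"] == window.chrom]
    tiles = window.tile_of(on_chrom["pos"].to_numpy(np.int64))
    keep = tiles >= 0
    cells = on_chrom["cell"].to_numpy(np.int64)[keep]
    tiles = tiles[keep]
    counts = sp.coo_matrix(
        (np.ones(len(tiles), dtype=np.int64), (cells, tiles)),
        shape=(n_cells, window.n_tiles),
    ).tocsr()
    if blacklist is not None and len(blacklist):
        bl = blacklist[blacklist["chrom"] == window.chrom]
        if len(bl):
            bs, be = _merge_intervals(bl["start"].to_numpy(), bl["end"].to_numpy())
            coords = window.tile_coords()
            # tile [s, e) overlaps interval [bs_j, be_j) iff s < be_j and e > bs_j
            j = np.searchsorted(bs, coords[:, 1], side="left") - 1
            hit = (j >= 0) & (coords[:, 0] < np.where(j >= 0, be[np.maximum(j, 0)], 0))
            if hit.any():
                counts = counts.tolil()
                counts[:, np.flatnonzero(hit)] = 0
                counts = counts.tocsr()
                counts.eliminate_zeros()
    return TileMatrix(gene_id=window.gene_id, counts=counts, window=window)


def compute_reads_in_tss(
    insertions: pd.DataFrame,
    tss: Sequence[tuple[str, int]],
    n_cells: int,
    window_bp: int = 2000,
) -> np.ndarray:
    """Per-cell count of insertions within +/- window_bp of any TSS, floored at 1.

    Overlapping TSS windows are merged so an insertion is counted once. Used
    as a sequencing-depth/quality normaliser when the metadata does not carry
    a precomputed value.
    """
    if not len(tss):
        raise ValueError("tss list must be non-empty")
    out = np.zeros(n_cells, dtype=np.int64)
    tss_df = pd.DataFrame(tss, columns=["chrom", "pos"])
    for chrom, grp in tss_df.groupby("chrom"):
        starts = grp["pos"].to_numpy(np.int64) - window_bp
        ends = grp["pos"].to_numpy(np.int64) + window_bp + 1  # inclusive of pos+window
        starts, ends = _merge_intervals(starts, ends)
        ins = insertions[insertions["chrom"] == chrom]
        hit = _in_intervals(ins["pos"].to_numpy(np.int64), starts, ends)
        np.add.at(out, ins["cell"].to_numpy(np.int64)[hit], 1)
    return np.maximum(out, 1)


def read_mtx(mtx_path, barcodes_path=None, features_path=None):
    """Matrix Market triplet + sidecars -> (csr matrix, barcodes, features)."""
    mat = sp.csr_matrix(scipy.io.mmread(mtx_path))
    barcodes = features = None
    if barcodes_path is not None:
        barcodes = pd.read_csv(barcodes_path, header=None, sep="\t")[0].tolist()
    if features_path is not None:
        features = pd.read_csv(features_path, header=None, sep="\t")[0].tolist()
    return mat, barcodes, features


def write_mtx(mat, mtx_path, barcodes=None, barcodes_path=None, features=None, features_path=None):
    scipy.io.mmwrite(str(mtx_path), sp.coo_matrix(mat))
    if barcodes is not None:
        pd.Series(barcodes).to_csv(barcodes_path, header=False, index=False)
    if features is not None:
        pd.Series(features).to_csv(features_path, header=False, index=False)


class ModelStore:
    """Keyed HDF5 container persisting one fitted gene model per group.

    Arrays round-trip bit-exactly. Use as a context manager::

        with ModelStore(path, "w") as store:
            store.save(results)
    """

    def __init__(self, path, mode: str = "r"):
        self._h5 = h5py.File(path, mode)

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()

    def close(self):
        self._h5.close()

    def genes(self) -> list[str]:
        return list(self._h5.keys())

    def save(self, results) -> None:
        """Persist a fitted TileExpressionResults under its gene_id."""
        g = results.gene_id or "gene"
        if g in self._h5:
            del self._h5[g]
        grp = self._h5.create_group(g)
        grp.create_dataset("coef", data=results.coef)
        grp.attrs["intercept"] = results.intercept
        grp.attrs["alpha"] = results.alpha
        grp.attrs["test_spearman"] = results.test_spearman
        grp.attrs["converged"] = results.converged
        grp.attrs["n_iter"] = results.n_iter
        grp.attrs["seed"] = results.split.seed
        grp.create_dataset("tile_min", data=results.scaler.min_)
        grp.create_dataset("tile_max", data=results.scaler.max_)
        grp.create_dataset("train_idx", data=results.split.train_idx)
        grp.create_dataset("test_idx", data=results.split.test_idx)
        grp.create_dataset(
            "fold_ids", data=results.split.fold_ids if results.split.fold_ids is not None else []
        )

    def load(self, gene_id: str):
        from .model import TileExpressionResults
        from .preprocess import SplitSpec, TileScaler

        grp = self._h5[gene_id]
        scaler = TileScaler()
        scaler.min_ = grp["tile_min"][:]
        scaler.max_ = grp["tile_max"][:]
        fold_ids = grp["fold_ids"][:]
        split = SplitSpec(
            train_idx=grp["train_idx"][:],
            test_idx=grp["test_idx"][:],
            fold_ids=fold_ids if len(fold_ids) else None,
            seed=int(grp.attrs["seed"]),
        )
        return TileExpressionResults(
            gene_id=gene_id,
            coef=grp["coef"][:],
            intercept=float(grp.attrs["intercept"]),
            alpha=float(grp.attrs["alpha"]),
            scaler=scaler,
            split=split,
            test_spearman=float(grp.attrs["test_spearman"]),
            converged=bool(grp.attrs["converged"]),
            n_iter=int(grp.attrs["n_iter"]),
        )
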