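"""Matched-background enrichment of variants in gene-linked tiles.

Candidate causal variants (fine-mapped GWAS hits, eQTLs, or curated
regulatory variants) are compared against common variants matched on minor
allele frequency bin, LD block and distance-to-gene class. Within each
matched group g,

    precision_g  = (# causal in linked tiles) / (# common in linked tiles)
    probability_g = (# causal in group, all tiles) / (# common in group, all tiles)
    enrichment_g = precision_g / probability_g

and the reported enrichment averages groups (equally weighted) within a unit
(trait or gene), then units. Uncertainty comes from a percentile bootstrap
over units.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GeneWindow
from .stats import bootstrap_mean

__all__ = [
    "MAF_BIN_EDGES",
    "EnrichmentResult",
    "distance_class",
    "maf_bin",
    "assign_ld_blocks",
    "assign_match_groups",
    "group_enrichment",
    "gwas_enrichment",
    "eqtl_enrichment",
    "regdb_enrichment",
    "enrichment_recall_curve",
]

logger = logging.getLogger(__name__)

MAF_BIN_EDGES = (0.01, 0.1)
PROXIMAL_TILES = 20


def maf_bin(maf) -> np.ndarray:
    """MAF category: '<0.01', '0.01-0.1' or '>0.1'."""
    maf = np.atleast_1d(np.asarray(maf, dtype=float))
    lo, hi = MAF_BIN_EDGES
    out = np.where(maf < lo, "<0.01", np.where(maf <= hi, "0.01-0.1", ">0.1"))
    return out


def distance_class(tile_index, window: GeneWindow, proximal_tiles: int = PROXIMAL_TILES):
    """Distance-to-gene class of a tile: gene body / promoter-proximal / downstream / distal.

    With f flank tiles per side, tiles [f, n-f) are the gene body; the
    min(proximal_tiles, f) tiles immediately upstream of the gene body (by
    strand) are promoter-proximal, the mirror set downstream, the rest distal.
    """
    idx = np.atleast_1d(np.asarray(tile_index, dtype=int))
    n = window.n_tiles
    if ((idx < 0) | (idx >= n)).any():
        bad = idx[(idx < 0) | (idx >= n)][0]
        raise IndexError(f"tile index {bad} outside window of {n} tiles")
    f = window.flank_tiles
    width = min(proximal_tiles, f)
    body = (idx >= f) & (idx < n - f)
    left = (idx >= f - width) & (idx < f)
    right = (idx >= n - f) & (idx < n - f + width)
    if window.strand == "+":
        proximal, downstream = left, right
    else:
        proximal, downstream = right, left
    out = np.full(idx.shape, "distal", dtype=object)
    out[body] = "gene body"
    out[proximal] = "promoter-proximal"
    out[downstream] = "downstream"
    return out if np.ndim(tile_index) else str(out[0])


def assign_ld_blocks(chrom, pos, ld_blocks: pd.DataFrame) -> np.ndarray:
    """LD block id per variant; variants outside all blocks get 'unassigned'."""
    chrom = np.asarray(chrom)
    pos = np.asarray(pos, dtype=np.int64)
    out = np.full(len(pos), "unassigned", dtype=object)
    for c, grp in ld_blocks.groupby("chrom"):
        grp = grp.sort_values("start")
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        names = (
            grp["name"].astype(str).to_numpy()
            if "name" in grp.columns and grp["name"].notna().all()
            else np.array([f"{c}:{s}-{e}" for s, e in zip(starts, ends)], dtype=object)
        )
        mask = chrom == c
        if not mask.any():
            continue
        i = np.searchsorted(starts, pos[mask], side="right") - 1
        ok = (i >= 0) & (pos[mask] < ends[np.maximum(i, 0)])
        sel = np.flatnonzero(mask)[ok]
        out[sel] = names[i[ok]]
    n_out = int((out == "unassigned").sum())
    if n_out:
        logger.info("%d variants fall outside all LD blocks", n_out)
    return out


def assign_match_groups(
    variants: pd.DataFrame,
    windows: dict[str, GeneWindow],
    ld_blocks: pd.DataFrame,
) -> pd.DataFrame:
    """Map each variant into the gene windows it falls in, with its match key.

    variants: columns variant_id, chrom, pos, maf (+ any flags). Returns one
    row per (variant, gene) with tile index, maf_bin, ld_block,
    distance_class and the combined group key.
    """
    variants = variants.reset_index(drop=True)
    bins = maf_bin(variants["maf"].to_numpy())
    blocks = assign_ld_blocks(
        variants["chrom"].to_numpy(), variants["pos"].to_numpy(), ld_blocks
    )
    # sort variants by (chrom, pos) once so each window is a binary-search slice
    all_pos = variants["pos"].to_numpy(np.int64)
    by_chrom = {}
    for chrom, idx in variants.groupby("chrom").groups.items():
        order = idx.to_numpy()[np.argsort(all_pos[idx.to_numpy()])]
        by_chrom[chrom] = (order, all_pos[order])
    rows = []
    for gene_id, win in windows.items():
        if win.chrom not in by_chrom:
            continue
        order, pos_sorted = by_chrom[win.chrom]
        lo = np.searchsorted(pos_sorted, win.window_start, side="left")
        hi = np.searchsorted(pos_sorted, win.window_end, side="left")
        on = order[lo:hi]
        if len(on) == 0:
            continue
        tiles = win.tile_of(variants.loc[on, "pos"].to_numpy(np.int64))
        dclass = distance_class(tiles, win)
        sub = variants.loc[on].copy()
        sub["gene_id"] = gene_id
        sub["tile"] = tiles
        sub["maf_bin"] = bins[on]
        sub["ld_block"] = blocks[on]
        sub["distance_class"] = dclass
        rows.append(sub)
    if not rows:
        return variants.iloc[0:0].assign(
            gene_id=None, tile=None, maf_bin=None, ld_block=None, distance_class=None, group=None
        )
    out = pd.concat(rows, ignore_index=True)
    out["group"] = (
        out["maf_bin"].astype(str)
        + "|"
        + out["ld_block"].astype(str)
        + "|"
        + out["distance_class"].astype(str)
    )
    return out


def _is_linked(assigned: pd.DataFrame, linked: pd.DataFrame) -> np.ndarray:
    """Whether each (variant, gene) row lands in a linked tile of that gene."""
    if len(linked) == 0 or len(assigned) == 0:
        return np.zeros(len(assigned), dtype=bool)
    idx = pd.MultiIndex.from_arrays([assigned["gene_id"], assigned["tile"]])
    linked_idx = pd.MultiIndex.from_arrays([linked["gene_id"], linked["tile"]])
    return idx.isin(linked_idx)


def group_enrichment(assigned: pd.DataFrame, in_linked: np.ndarray) -> float | None:
    """Equal-weight average over matched groups of precision/probability.

    assigned must carry boolean columns is_causal and is_common plus the
    group key. Groups with zero common variants in linked tiles (or zero
    causal variants overall) are excluded; returns None when no group is
    computable.
    """
    df = assigned.assign(linked=in_linked)
    vals = []
    for _, grp in df.groupby("group", sort=False):
        causal_all = int(grp["is_causal"].sum())
        common_all = int(grp["is_common"].sum())
        common_linked = int((grp["is_common"] & grp["linked"]).sum())
        if causal_all == 0 or common_all == 0 or common_linked == 0:
            continue
        causal_linked = int((grp["is_causal"] & grp["linked"]).sum())
        precision = causal_linked / common_linked
        probability = causal_all / common_all
        vals.append(precision / probability)
    return float(np.mean(vals)) if vals else None


@dataclass
class EnrichmentResult:
    """Mean enrichment over units with a bootstrap 95% CI."""

    kind: str
    per_unit: pd.Series  # enrichment per trait/gene (or per group for regdb)
    mean: float
    ci: tuple[float, float]
    n_bootstrap: int

    def summary(self) -> str:
        return (
            f"{self.kind} enrichment over {len(self.per_unit)} units: "
            f"{self.mean:.3f} (95% CI {self.ci[0]:.3f}-{self.ci[1]:.3f}, "
            f"{self.n_bootstrap} bootstrap iterations)"
        )


def _unit_enrichment(
    assigned: pd.DataFrame, linked: pd.DataFrame, unit_col: str
) -> pd.Series:
    """Per-unit (trait or gene) enrichment.

    The common-variant background is shared across traits; for gene units the
    universe is restricted to that gene's window. Units with no causal
    variants in the universe are excluded.
    """
    df = assigned.assign(linked=_is_linked(assigned, linked))
    common = df[df["is_common"]]
    causal = df[df["is_causal"]]
    if unit_col == "gene":
        # an eQTL counts only in its own gene's window; background per window
        causal = causal[causal["gene"] == causal["gene_id"]]
        key = ["gene_id", "group"]
        com_grp = common.groupby(key)
        ca_grp = causal.groupby(key)
    else:
        # trait units share one common background across all windows
        key = ["group"]
        com_grp = common.groupby(key)
        ca_grp = causal.groupby([unit_col] + key)
    com = pd.concat(
        [com_grp.size().rename("co"), com_grp["linked"].sum().rename("col")], axis=1
    )
    ca = pd.concat(
        [ca_grp.size().rename("ca"), ca_grp["linked"].sum().rename("cal")], axis=1
    ).reset_index()
    if unit_col == "gene":
        tab = ca.join(com, on=key)
        tab["unit"] = tab["gene_id"]
    else:
        tab = ca.join(com, on=key)
        tab["unit"] = tab[unit_col]
    tab[["co", "col"]] = tab[["co", "col"]].fillna(0)
    valid = (tab["ca"] > 0) & (tab["co"] > 0) & (tab["col"] > 0)
    tab = tab[valid]
    tab = tab.assign(enrichment=(tab["cal"] / tab["col"]) / (tab["ca"] / tab["co"]))
    out = tab.groupby("unit")["enrichment"].mean()
    out.index.name = None
    return out.sort_index().astype(float)


def gwas_enrichment(
    linked: pd.DataFrame,
    assigned: pd.DataFrame,
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> EnrichmentResult:
    """Per-trait matched-group enrichment of fine-mapped GWAS variants.

    assigned: output of assign_match_groups with columns trait, is_causal,
    is_common; linked: gene-linked tiles (gene_id, tile). Bootstrap is over
    traits.
    """
    per_trait = _unit_enrichment(assigned, linked, "trait")
    if per_trait.empty:
        return EnrichmentResult("gwas", per_trait, 0.0, (0.0, 0.0), n_bootstrap)
    mean, ci = bootstrap_mean(per_trait.to_numpy(), n_iter=n_bootstrap, seed=seed)
    return EnrichmentResult("gwas", per_trait, mean, ci, n_bootstrap)


def eqtl_enrichment(
    linked: pd.DataFrame,
    assigned: pd.DataFrame,
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> EnrichmentResult:
    """Per-gene enrichment of fine-mapped eQTLs, restricted to each gene's window.

    A causal eQTL counts only for its own gene, against the common variants of
    that gene's window; bootstrap is over genes.
    """
    per_gene = _unit_enrichment(assigned, linked, "gene")
    if per_gene.empty:
        return EnrichmentResult("eqtl", per_gene, 0.0, (0.0, 0.0), n_bootstrap)
    mean, ci = bootstrap_mean(per_gene.to_numpy(), n_iter=n_bootstrap, seed=seed)
    return EnrichmentResult("eqtl", per_gene, mean, ci, n_bootstrap)


def regdb_enrichment(
    linked: pd.DataFrame,
    assigned: pd.DataFrame,
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> EnrichmentResult:
    """Enrichment of curated regulatory variants, averaged over matched groups.

    is_causal marks the regulatory set (e.g. rank 1a, probability > 0.9);
    there is no per-trait unit, so the bootstrap resamples matched groups.
    """
    in_linked = _is_linked(assigned, linked)
    df = assigned.assign(linked=in_linked)
    vals = {}
    for key, grp in df.groupby("group", sort=True):
        causal_all = int(grp["is_causal"].sum())
        common_all = int(grp["is_common"].sum())
        common_linked = int((grp["is_common"] & grp["linked"]).sum())
        if causal_all == 0 or common_all == 0 or common_linked == 0:
            continue
        precision = int((grp["is_causal"] & grp["linked"]).sum()) / common_linked
        vals[key] = precision / (causal_all / common_all)
    per_group = pd.Series(vals, dtype=float)
    if per_group.empty:
        return EnrichmentResult("regdb", per_group, 0.0, (0.0, 0.0), n_bootstrap)
    mean, ci = bootstrap_mean(per_group.to_numpy(), n_iter=n_bootstrap, seed=seed)
    return EnrichmentResult("regdb", per_group, mean, ci, n_bootstrap)


def enrichment_recall_curve(
    ranked_tiles: pd.DataFrame,
    assigned: pd.DataFrame,
    unit_col: str = "trait",
    step: int = 10,
) -> pd.DataFrame:
    """Mean enrichment as a function of the number of top-ranked linked tiles.

    ranked_tiles must be sorted by significance (best first) with gene_id and
    tile columns; at each cutoff k the enrichment is recomputed on the top-k
    tiles. Returns a frame with columns n_tiles, enrichment.
    """
    ks = list(range(step, len(ranked_tiles) + 1, step))
    if not ks or ks[-1] != len(ranked_tiles):
        ks.append(len(ranked_tiles))
    rows = []
    for k in ks:
        if k == 0:
            continue
        per_unit = _unit_enrichment(assigned, ranked_tiles.head(k), unit_col)
        if not per_unit.empty:
            rows.append((k, float(per_unit.mean())))
    return pd.DataFrame(rows, columns=["n_tiles", "enrichment"])
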