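import numpy as np
import pandas as pd
import pytest

from tilelink.enrichment import (
    assign_ld_blocks,
    assign_match_groups,
    distance_class,
    enrichment_recall_curve,
    eqtl_enrichment,
    group_enrichment,
    gwas_enrichment,
    maf_bin,
    regdb_enrichment,
)
from tilelink.io import GeneAnnotation, make_gene_window
from tilelink.simulate import simulate_variants


def _window(strand="+", flank=250_000, length=60_000):
    g = GeneAnnotation("g", "chr1", 400_000, 400_000 + length, strand)
    return make_gene_window(g, flank=flank)


@pytest.fixture(scope="module")
def universe():
    """Synthetic variant universe with a planted enrichment factor of 4."""
    genes = [
        GeneAnnotation(f"g{i}", "chr1", 50_000 + i * 250_000, 60_000 + i * 250_000, "+")
        for i in range(4)
    ]
    windows = {g.gene_id: make_gene_window(g, flank=20_000, tile_size=500) for g in genes}
    rng = np.random.default_rng(5)
    enh = {g.gene_id: np.sort(rng.choice(100, 5, replace=False)) for g in genes}
    linked = pd.DataFrame(
        [(g, t) for g in windows for t in enh[g]], columns=["gene_id", "tile"]
    )
    variants, ld = simulate_variants(
        windows, enh, n_common_per_gene=300, n_causal_per_gene=60,
        n_traits=4, enrichment_factor=4.0, seed=5,
    )
    assigned = assign_match_groups(variants, windows, ld)
    return assigned, linked


class TestDistanceClass:
    def test_full_scale_layout(self):
        win = _window()  # 500 flank tiles per side, 120 gene-body tiles
        assert distance_class(0, win) == "distal"
        assert distance_class(480, win) == "promoter-proximal"
        assert distance_class(479, win) == "distal"
        assert distance_class(600, win) == "gene body"
        assert distance_class(win.n_tiles - 500, win) == "downstream"
        assert distance_class(win.n_tiles - 481, win) == "downstream"
        assert distance_class(win.n_tiles - 480, win) == "distal"

    def test_minus_strand_mirrors(self):
        win = _window(strand="-")
        assert distance_class(480, win) == "downstream"
        assert distance_class(win.n_tiles - 500, win) == "promoter-proximal"

    def test_partition_counts(self):
        """Every tile gets exactly one class with the stated widths."""
        win = _window()
        classes = distance_class(np.arange(win.n_tiles), win)
        counts = pd.Series(classes).value_counts()
        assert counts["promoter-proximal"] == 20
        assert counts["downstream"] == 20
        assert counts["gene body"] == win.n_tiles - 1000
        assert counts.sum() == win.n_tiles

    def test_narrow_flank_rescales(self):
        win = _window(flank=5_000)  # 10 flank tiles: proximal width min(20, 10)
        classes = distance_class(np.arange(win.n_tiles), win)
        assert (pd.Series(classes).value_counts()["promoter-proximal"]) == 10

    def test_out_of_range(self):
        with pytest.raises(IndexError):
            distance_class(10_000_000, _window())


class TestMatching:
    def test_maf_bins(self):
        assert list(maf_bin([0.005, 0.05, 0.3])) == ["<0.01", "0.01-0.1", ">0.1"]
        assert maf_bin(0.01)[0] == "0.01-0.1"  # boundary goes to middle bin

    def test_ld_block_assignment(self):
        ld = pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "start": [0, 100], "end": [100, 200], "name": ["a", "b"]}
        )
        out = assign_ld_blocks(np.array(["chr1", "chr1", "chr2"]), np.array([5, 150, 5]), ld)
        assert list(out) == ["a", "b", "unassigned"]

    def test_match_groups_unique_per_variant_gene(self):
        win = _window(flank=20_000, length=10_000)
        variants = pd.DataFrame(
            {
                "variant_id": ["v1", "v2"],
                "chrom": ["chr1", "chr1"],
                "pos": [win.window_start + 100, win.window_start + 20_250],
                "maf": [0.005, 0.2],
            }
        )
        ld = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [10**9], "name": ["blk"]})
        out = assign_match_groups(variants, {"g": win}, ld)
        assert len(out) == 2
        assert out.loc[out.variant_id == "v1", "distance_class"].iloc[0] == "distal"
        assert out.loc[out.variant_id == "v2", "distance_class"].iloc[0] == "gene body"
        assert out["group"].str.count(r"\|").eq(2).all()


class TestEnrichmentFormulas:
    def test_single_group_arithmetic(self):
        # 2 causal & 4 common in linked; 10 causal & 100 common overall -> 5.0
        df = pd.DataFrame(
            {
                "group": "g1",
                "is_causal": [True] * 10 + [False] * 100,
                "is_common": [False] * 10 + [True] * 100,
            }
        )
        linked = np.zeros(110, dtype=bool)
        linked[:2] = True  # 2 causal
        linked[10:14] = True  # 4 common
        assert group_enrichment(df, linked) == pytest.approx(5.0)

    def test_no_causal_in_linked_gives_zero(self):
        df = pd.DataFrame(
            {"group": "g", "is_causal": [True, False, False], "is_common": [False, True, True]}
        )
        linked = np.array([False, True, False])
        assert group_enrichment(df, linked) == 0.0

    def _brute_force(self, assigned, linked_keys, unit_col):
        """Counting oracle: recompute per-unit enrichment with explicit loops."""
        vals = {}
        rows = assigned.to_dict("records")
        for r in rows:
            r["linked"] = (r["gene_id"], r["tile"]) in linked_keys
        units = sorted({r[unit_col] for r in rows if r["is_causal"] and pd.notna(r[unit_col])})
        for unit in units:
            if unit_col == "gene":
                causal = [r for r in rows if r["is_causal"] and r["gene"] == unit and r["gene_id"] == unit]
                common = [r for r in rows if r["is_common"] and r["gene_id"] == unit]
            else:
                causal = [r for r in rows if r["is_causal"] and r[unit_col] == unit]
                common = [r for r in rows if r["is_common"]]
            if not causal:
                continue
            groups = {r["group"] for r in causal + common}
            es = []
            for g in groups:
                ca = sum(1 for r in causal if r["group"] == g)
                co = sum(1 for r in common if r["group"] == g)
                col = sum(1 for r in common if r["group"] == g and r["linked"])
                if ca == 0 or co == 0 or col == 0:
                    continue
                cal = sum(1 for r in causal if r["group"] == g and r["linked"])
                es.append((cal / col) / (ca / co))
            if es:
                vals[unit] = float(np.mean(es))
        return vals

    def test_gwas_equals_counting_oracle(self, universe):
        assigned, linked = universe
        res = gwas_enrichment(linked, assigned, seed=0)
        oracle = self._brute_force(assigned, set(zip(linked.gene_id, linked.tile)), "trait")
        assert set(res.per_unit.index) == set(oracle)
        for unit, v in oracle.items():
            assert res.per_unit[unit] == pytest.approx(v)

    def test_eqtl_equals_counting_oracle(self, universe):
        assigned, linked = universe
        res = eqtl_enrichment(linked, assigned, seed=0)
        oracle = self._brute_force(assigned, set(zip(linked.gene_id, linked.tile)), "gene")
        assert set(res.per_unit.index) == set(oracle)
        for unit, v in oracle.items():
            assert res.per_unit[unit] == pytest.approx(v)

    def test_regdb_matches_group_oracle(self, universe):
        assigned, linked = universe
        res = regdb_enrichment(linked, assigned, seed=0)
        linked_keys = set(zip(linked.gene_id, linked.tile))
        rows = assigned.to_dict("records")
        for r in rows:
            r["linked"] = (r["gene_id"], r["tile"]) in linked_keys
        for g in res.per_unit.index:
            grp = [r for r in rows if r["group"] == g]
            cal = sum(1 for r in grp if r["is_causal"] and r["linked"])
            col = sum(1 for r in grp if r["is_common"] and r["linked"])
            ca = sum(1 for r in grp if r["is_causal"])
            co = sum(1 for r in grp if r["is_common"])
            assert res.per_unit[g] == pytest.approx((cal / col) / (ca / co))

    def test_planted_enrichment_detected(self, universe):
        assigned, linked = universe
        res = gwas_enrichment(linked, assigned, seed=0)
        assert res.mean > 1.5  # planted factor 4 concentrates causal in linked tiles
        assert res.ci[0] <= res.mean <= res.ci[1]


class TestRecallCurve:
    def test_full_cutoff_matches_overall(self):
        genes = [GeneAnnotation("g0", "chr1", 50_000, 60_000, "+")]
        windows = {"g0": make_gene_window(genes[0], flank=20_000, tile_size=500)}
        enh = {"g0": np.arange(0, 20)}
        variants, ld = simulate_variants(
            windows, enh, n_common_per_gene=400, n_causal_per_gene=80,
            n_traits=3, enrichment_factor=5.0, seed=9,
        )
        assigned = assign_match_groups(variants, windows, ld)
        ranked = pd.DataFrame({"gene_id": "g0", "tile": enh["g0"]})
        curve = enrichment_recall_curve(ranked, assigned, unit_col="trait", step=5)
        overall = gwas_enrichment(ranked, assigned, seed=0)
        assert curve["n_tiles"].iloc[-1] == len(ranked)
        assert curve["enrichment"].iloc[-1] == pytest.approx(overall.per_unit.mean())
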