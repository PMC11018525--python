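import numpy as np
import pandas as pd
import pytest

from tilelink.interpret import (
    add_fdr,
    correlation_comparison,
    interaction_score_comparison,
    linked_tiles,
    shapley_profile,
    shapley_scores,
    tile_significance,
)
from tilelink.pipeline import run_linking
from tilelink.simulate import SimulationSpec, simulate_multiome


class TestShapley:
    def test_profile_arithmetic(self):
        shap = shapley_profile(np.array([2.0, 0.0]), np.array([0.8, 0.9]), np.array([0.3, 0.1]))
        assert shap[0] == pytest.approx(1.0)  # 2 * (0.8 - 0.3)
        assert shap[1] == 0.0  # zero coefficient -> zero attribution

    def test_local_accuracy_and_z_standardization(self, fitted, small_ds):
        """Sum of Shapley values equals the pseudobulk linear predictor minus
        the background linear predictor, exactly; z-scores are standardized."""
        res, X = fitted
        tr = res.split.train_idx
        Xs = res.scaler.transform(X[tr])
        ct = small_ds.cells["cell_type"].to_numpy()[tr]
        tables = shapley_scores(res, Xs, ct, seed=5, n_iter=50)
        assert tables  # both simulated types exceed the 100-cell floor
        background = Xs.mean(axis=0)
        # local accuracy on an arbitrary pseudobulk profile, against an
        # independent linear-predictor computation
        profile = Xs[:37].mean(axis=0)
        shap = shapley_profile(res.coef, profile, background)
        assert shap.sum() == pytest.approx(
            profile @ res.coef - background @ res.coef, abs=1e-10
        )
        for tab in tables.values():
            assert tab.z.mean() == pytest.approx(0.0, abs=1e-10)
            assert tab.z.std() == pytest.approx(1.0, abs=1e-10)

    def test_small_cell_type_skipped(self, fitted):
        res, X = fitted
        tr = res.split.train_idx
        Xs = res.scaler.transform(X[tr])
        ct = np.array(["rare"] * 10 + ["bulk"] * (len(tr) - 10))
        tables = shapley_scores(res, Xs, ct, seed=0, n_iter=10)
        assert set(tables) == {"bulk"}

    def test_pseudobulk_equal_to_background_gives_zero(self, fitted):
        res, _ = fitted
        bg = np.full(res.n_tiles, 0.4)
        assert not shapley_profile(res.coef, bg, bg).any()

    def test_seeded_determinism(self, fitted, small_ds):
        res, X = fitted
        tr = res.split.train_idx
        Xs = res.scaler.transform(X[tr])
        ct = small_ds.cells["cell_type"].to_numpy()[tr]
        a = shapley_scores(res, Xs, ct, seed=3, n_iter=20)
        b = shapley_scores(res, Xs, ct, seed=3, n_iter=20)
        for k in a:
            assert np.array_equal(a[k].values, b[k].values)


class TestTileSignificance:
    def test_zero_coefficient_gives_p_one(self, fitted, small_ds):
        res, X = fitted
        te = res.split.test_idx
        Xs = res.scaler.transform(X[te])
        ct = small_ds.cells["cell_type"].to_numpy()[te]
        zero_tiles = np.flatnonzero(res.coef == 0)[:3]
        sig = tile_significance(res, Xs, res.model.y[te], ct, tiles=zero_tiles)
        assert (sig["p"] == 1.0).all()

    def test_planted_tile_significant_in_expressing_type(self, fitted, small_ds):
        res, X = fitted
        te = res.split.test_idx
        Xs = res.scaler.transform(X[te])
        ct = small_ds.cells["cell_type"].to_numpy()[te]
        strong = int(np.argmax(res.coef))
        sig = tile_significance(res, Xs, res.model.y[te], ct, tiles=[strong])
        p_on = sig[sig.cell_type == "type_0"]["p"].iloc[0]
        p_off = sig[sig.cell_type == "type_1"]["p"].iloc[0]
        # enhancer accessible only in type_0: removing it hurts there, not in type_1
        assert p_on < 1e-2
        assert p_off > 0.05
        assert p_on < p_off

    def test_fdr_column_properties(self, fitted, small_ds):
        res, X = fitted
        te = res.split.test_idx
        Xs = res.scaler.transform(X[te])
        ct = small_ds.cells["cell_type"].to_numpy()[te]
        sig = add_fdr(tile_significance(res, Xs, res.model.y[te], ct))
        assert (sig["q"] >= sig["p"] - 1e-12).all()
        assert (sig["q"] <= 1.0).all()


class TestLinkedTiles:
    def test_thresholds_and_recovery(self, small_ds):
        out = run_linking(small_ds, seed=11)
        linked = out["linked"]
        assert (linked["z"] > 0.5).all()
        assert (linked["q"] < 1e-3).all()
        # linked tiles concentrate on the planted enhancers of the expressing type
        assert set(linked["cell_type"]) == {"type_0"}
        for gid in small_ds.gene_ids:
            truth = set(map(int, small_ds.truth[gid]["active_tiles"]))
            called = set(map(int, linked[linked.gene_id == gid]["tile"]))
            if called:
                assert called <= truth

    def test_low_correlation_gene_excluded(self, small_ds):
        out = run_linking(small_ds, seed=11, min_corr=2.0)  # unattainable rho
        assert out["linked"].empty


class TestCorrelationComparison:
    def test_better_predictor_wins(self, rng):
        obs = rng.normal(size=300)
        good = obs + rng.normal(0, 0.5, 300)
        bad = obs + rng.normal(0, 2.0, 300)
        cmp = correlation_comparison(good, bad, obs)
        assert cmp["rho12"] > cmp["rho13"]
        assert cmp["p"] < 0.01
        # determinant-based |S| stays in [0, 1] for a valid correlation triple
        s = (
            1
            - (cmp["rho12"] ** 2 + cmp["rho13"] ** 2 + cmp["rho23"] ** 2)
            + 2 * cmp["rho12"] * cmp["rho13"] * cmp["rho23"]
        )
        assert 0 <= s <= 1


class TestInteractionComparison:
    def _setup(self, rng, shift, span=2):
        n_tiles = 400
        shap = rng.normal(0, 1, n_tiles)
        acc = rng.uniform(0.5, 2.0, n_tiles)
        interactions = [np.arange(i, i + span) for i in range(0, 100, span)]
        for it in interactions:
            shap[it] += shift
        return shap, interactions, acc

    def test_null_is_uniform(self, rng):
        # single-tile interactions: under exchangeability p is not small
        shap, inter, acc = self._setup(rng, 0.0, span=1)
        p, nf, nb = interaction_score_comparison(shap, inter, acc, seed=0)
        assert 0.05 < p
        assert nf > 0 and nb > 0

    def test_shifted_scores_detected(self, rng):
        shap, inter, acc = self._setup(rng, 1.0)
        p, _, _ = interaction_score_comparison(shap, inter, acc, seed=0)
        assert p < 0.01

    def test_max_over_spanned_tiles(self):
        shap = np.array([0.2, 0.9, -0.5, 0.0])
        acc = np.array([1.0, 1.0, 1.0, 1.0])
        p, nf, nb = interaction_score_comparison(
            shap, [np.array([0, 1])], acc, reference_accessibility=np.array([0.0]), seed=0
        )
        # single interaction scored as max(0.2, 0.9): beats both background tiles
        assert nf == 1
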