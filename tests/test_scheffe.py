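import numpy as np
import pandas as pd
import pytest

from dietmix.design import STUDY_SPACE, TESTED_BLENDS, reference_design
from dietmix.reference import reference_surfaces
from dietmix.scheffe import (
    MODEL_LADDER,
    CoefficientSurface,
    arcsine_sqrt,
    backward_eliminate,
    design_matrix,
    fit,
    inv_arcsine_sqrt,
    lack_of_fit,
    ladder_termset,
    predict,
    press_stats,
    sequential_selection,
)
from dietmix.synthetic import simulate_runs

from conftest import loo_oracle

BLENDS = ["yeast_pct", "cornflour_pct", "corncob_pct"]


def _runs_from_blends(blends, responses):
    df = pd.DataFrame(blends, columns=BLENDS)
    df.insert(0, "run_id", np.arange(1, len(df) + 1))
    df["mixture_no"] = 0
    df["n_larvae"] = 25
    for col in ("pupation", "duration_days", "pupal_weight_mg", "emergence"):
        df[col] = np.nan
    df["duration_days"] = responses
    df["excluded_responses"] = ""
    return df


class TestDesignMatrix:
    def test_corner_row_linear(self, design40):
        X = design_matrix(design40, ladder_termset("linear"))
        corner = design40[BLENDS].to_numpy()[:, 0] == 6.0
        np.testing.assert_allclose(X[corner], [[1.0, 0.0, 0.0]] * corner.sum(), atol=1e-12)

    def test_higher_order_term_values(self):
        ts = ladder_termset("special_quartic")
        j = ts.names.index("A^2*B*C")
        from dietmix.design import from_pseudo

        runs = _runs_from_blends([from_pseudo((0.5, 0.25, 0.25))], [1.0])
        X = design_matrix(runs, ts)
        assert X[0, j] == pytest.approx(0.5**2 * 0.25 * 0.25, abs=1e-12)

    def test_centroid_interaction(self):
        ts = ladder_termset("quadratic")
        runs = _runs_from_blends([(4.0, 6.3, 20.0)], [1.0])
        X = design_matrix(runs, ts)
        assert X[0, ts.names.index("A*B")] == pytest.approx(1 / 9, abs=1e-12)


class TestLadder:
    @pytest.mark.parametrize(
        "label,n_terms",
        [
            ("mean", 1),
            ("linear", 3),
            ("quadratic", 6),
            ("special_cubic", 7),
            ("cubic", 10),
            ("special_quartic", 9),
            ("quartic", 15),
        ],
    )
    def test_term_counts(self, label, n_terms):
        assert len(ladder_termset(label)) == n_terms

    def test_ladder_is_fixed_sequence(self):
        assert MODEL_LADDER[0] == "mean" and MODEL_LADDER[-1] == "quartic"


class TestFit:
    def test_interpolating_fit_recovers_corner_responses(self):
        # duplicated corner blends with replicate-identical responses:
        # the linear model interpolates the corner means exactly
        corners = [TESTED_BLENDS[1], TESTED_BLENDS[19], TESTED_BLENDS[15]]
        runs = _runs_from_blends(corners * 2, [1.0, 2.0, 3.0] * 2)
        mf = fit(runs, "duration_days", ladder_termset("linear"))
        np.testing.assert_allclose(mf.coef, [1.0, 2.0, 3.0], atol=1e-10)
        assert np.sum(mf.resid**2) == pytest.approx(0, abs=1e-18)
        assert mf.r2 == pytest.approx(1.0)

    @pytest.mark.parametrize("resp", ["pupation", "duration_days", "pupal_weight_mg", "emergence"])
    def test_noise_free_simulation_recovers_truth(self, design40, noise_free_runs, resp):
        surf = reference_surfaces()[resp]
        mf = fit(noise_free_runs, resp, surf.termset)
        np.testing.assert_allclose(mf.coef, surf.coef, atol=1e-9)

    def test_linear_coefficients_equal_corner_predictions(self, noisy_runs):
        mf = fit(noisy_runs, "pupation", ladder_termset("linear"))
        preds = mf.predict(STUDY_SPACE.corners)
        np.testing.assert_allclose(preds, mf.coef, atol=1e-12)

    def test_mixture_df_convention(self, noisy_runs):
        mf = fit(noisy_runs, "pupation", ladder_termset("linear"))
        assert (mf.df_model, mf.df_resid) == (2, 37)

    def test_missing_response_rows_dropped(self, noisy_runs):
        runs = noisy_runs.copy()
        runs.loc[runs.index[:3], "pupal_weight_mg"] = np.nan
        mf = fit(runs, "pupal_weight_mg", ladder_termset("linear"))
        assert mf.n_obs == 37
        # other responses untouched
        assert fit(runs, "pupation", ladder_termset("linear")).n_obs == 40

    def test_aliased_terms_raise(self):
        corners = [TESTED_BLENDS[1], TESTED_BLENDS[19], TESTED_BLENDS[15]]
        runs = _runs_from_blends(corners * 3, list(range(9)))
        with pytest.raises(np.linalg.LinAlgError):
            fit(runs, "duration_days", ladder_termset("quadratic"))

    def test_transform_domain_checked(self, noisy_runs):
        runs = noisy_runs.copy()
        runs.loc[runs.index[0], "duration_days"] = 9.5
        with pytest.raises(ValueError):
            fit(runs, "duration_days", ladder_termset("linear"), transform="arcsine_sqrt")


class TestLackOfFit:
    def test_study_design_linear_df(self, noisy_runs):
        mf = fit(noisy_runs, "pupation", ladder_termset("linear"))
        assert (mf.lof["df_lof"], mf.lof["df_pe"]) == (16, 21)

    def test_singleton_exclusion_preserves_pure_error_df(self, noisy_runs):
        # removing a run of an unreplicated blend: 39 runs, 18 blends,
        # 8-term reduced special quartic -> LOF df (10, 21), model df (7, 31)
        singleton = int(noisy_runs.loc[noisy_runs.mixture_no == 7, "run_id"].iloc[0])
        ts = reference_surfaces()["duration_days"].termset
        mf = fit(noisy_runs, "duration_days", ts, exclude=(singleton,))
        assert (mf.lof["df_lof"], mf.lof["df_pe"]) == (10, 21)
        assert (mf.df_model, mf.df_resid) == (7, 31)

    def test_no_replicates_raises(self):
        blends = list(TESTED_BLENDS.values())[:8]
        runs = _runs_from_blends(blends, np.arange(8.0))
        mf = fit(runs, "duration_days", ladder_termset("linear"), with_lof=False)
        with pytest.raises(ValueError, match="replicate"):
            lack_of_fit(mf, runs)

    def test_identical_replicates_zero_pure_error_guard(self):
        corners = [TESTED_BLENDS[1], TESTED_BLENDS[19], TESTED_BLENDS[15]]
        runs = _runs_from_blends(corners * 2 + [TESTED_BLENDS[4]], [1, 2, 3, 1, 2, 3, 9.0])
        mf = fit(runs, "duration_days", ladder_termset("linear"))
        assert mf.lof["ss_pe"] == pytest.approx(0.0, abs=1e-18)
        assert np.isinf(mf.lof["F"]) or mf.lof["F"] == 0.0


class TestPress:
    def test_hat_identity_equals_explicit_loo(self, small_fits):
        for mf in small_fits:
            oracle = loo_oracle(mf)
            assert mf.press == pytest.approx(oracle["press"], abs=1e-8)
            ps = press_stats(mf)
            assert ps["press"] == pytest.approx(oracle["press"], abs=1e-8)

    def test_r2_pred_below_r2(self, small_fits):
        for mf in small_fits:
            assert mf.r2_pred <= mf.r2_adj + 1e-12 <= mf.r2 + 1e-12
            assert mf.press > 0


class TestAdequatePrecision:
    def test_constant_response_gives_zero(self, design40):
        runs = design40.copy()
        runs["duration_days"] = 10.0
        mf = fit(runs, "duration_days", ladder_termset("linear"))
        assert mf.adequate_precision == pytest.approx(0.0, abs=1e-6)

    def test_zero_noise_gives_infinite_precision(self, noise_free_runs):
        surf = reference_surfaces()["duration_days"]
        mf = fit(noise_free_runs, "duration_days", surf.termset)
        assert np.isinf(mf.adequate_precision)

    def test_matches_definition(self, noisy_runs):
        mf = fit(noisy_runs, "pupation", ladder_termset("linear"))
        p, n = 3, mf.n_obs
        expected = (mf.fitted.max() - mf.fitted.min()) / np.sqrt(p * mf.sigma**2 / n)
        assert mf.adequate_precision == pytest.approx(expected, rel=1e-12)


class TestSequentialSelection:
    def test_type1_ss_conserves_model_ss(self, noisy_runs):
        sel = sequential_selection(noisy_runs, "duration_days")
        ok = sel.table.loc[~sel.table["aliased"].astype(bool)]
        top = ok.iloc[-1]["order"]
        mf = fit(noisy_runs, "duration_days", ladder_termset(top))
        ss_model = float(np.sum((mf.fitted - mf.y.mean()) ** 2))
        assert ok["seq_ss"].sum() == pytest.approx(ss_model, abs=1e-8)

    def test_saturating_design_flags_higher_orders_aliased(self):
        corners = [TESTED_BLENDS[1], TESTED_BLENDS[19], TESTED_BLENDS[15]]
        runs = _runs_from_blends(corners * 2, [1.0, 2.0, 3.1, 1.1, 2.2, 2.9])
        sel = sequential_selection(runs, "duration_days")
        tab = sel.table.set_index("order")
        assert sel.chosen == "linear"
        assert bool(tab.loc["quartic", "aliased"]) and bool(tab.loc["quadratic", "aliased"])

    def test_chosen_order_never_aliased(self, noisy_runs):
        for resp in ("pupation", "duration_days"):
            sel = sequential_selection(noisy_runs, resp)
            row = sel.table.set_index("order").loc[sel.chosen]
            assert not bool(row["aliased"])


class TestBackwardElimination:
    def test_hierarchy_keeps_contained_terms(self, design40):
        # strong quartic interactions with weak two-way terms: the ns two-way
        # terms must survive because A^2*B*C / A*B^2*C contain them
        runs = simulate_runs(design40, seed=0)
        mf = fit(runs, "duration_days", ladder_termset("special_quartic"))
        red = backward_eliminate(mf, runs)
        names = set(red.termset.names)
        assert {"A", "B", "C"} <= names
        for higher, lower in [("A^2*B*C", {"A*B", "A*C", "B*C"}),
                              ("A*B^2*C", {"A*B", "A*C", "B*C"})]:
            if higher in names:
                assert lower <= names

    def test_null_interactions_reduce_to_linear(self, design40):
        rng = np.random.default_rng(5)
        runs = design40.copy()
        surf = reference_surfaces()["pupation"]
        runs["pupation"] = surf.predict(runs[BLENDS].to_numpy()) + rng.normal(0, 0.08, 40)
        mf = fit(runs, "pupation", ladder_termset("quadratic"))
        red = backward_eliminate(mf, runs)
        assert red.termset.names == ["A", "B", "C"]

    def test_linear_terms_never_removed(self, design40):
        runs = design40.copy()
        rng = np.random.default_rng(11)
        runs["duration_days"] = 10.0 + rng.normal(0, 0.5, 40)  # pure noise
        mf = fit(runs, "duration_days", ladder_termset("quadratic"))
        red = backward_eliminate(mf, runs)
        assert {"A", "B", "C"} <= set(red.termset.names)


class TestPredict:
    def test_corner_prediction_equals_term_A(self, noisy_runs):
        mf = fit(noisy_runs, "duration_days", ladder_termset("quadratic"))
        out = predict(mf, [TESTED_BLENDS[1]])
        assert out["predicted"].iloc[0] == pytest.approx(mf.coef_named("A"), abs=1e-12)
        lo, hi = mf.ci_named("A")
        assert out["ci_low"].iloc[0] == pytest.approx(lo, abs=1e-12)
        assert out["ci_high"].iloc[0] == pytest.approx(hi, abs=1e-12)

    def test_published_duration_surface_at_operability_corner(self):
        surf = reference_surfaces()["duration_days"]
        val = surf.predict([(5.27, 6.03, 19.0)])[0]
        assert val == pytest.approx(9.457, abs=0.005)  # just inside the 9.46 limit

    def test_arcsine_back_transform_round_trip(self):
        y = np.array([0.0, 0.25, 0.9, 1.0])
        np.testing.assert_allclose(inv_arcsine_sqrt(arcsine_sqrt(y)), y, atol=1e-12)

    def test_transformed_corner_prediction_back_transforms(self, design40):
        rng = np.random.default_rng(2)
        surf = reference_surfaces()["emergence"]
        runs = design40.copy()
        runs["emergence"] = np.clip(
            surf.predict(runs[BLENDS].to_numpy()) + rng.normal(0, 0.05, 40), 0.02, 0.98
        )
        mf = fit(runs, "emergence", ladder_termset("linear"), transform="arcsine_sqrt")
        pred = mf.predict([TESTED_BLENDS[1]])[0]
        assert pred == pytest.approx(np.sin(mf.coef_named("A")) ** 2, abs=1e-12)
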