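import itertools

import numpy as np
import pytest

from dietmix.cost import CostSpec, study_cost_spec
from dietmix.design import STUDY_SPACE, TESTED_BLENDS
from dietmix.optimize import (
    Criterion,
    criteria_from_reference,
    evaluate_grid,
    max_savings_report,
    operability_region,
    overlay_export,
    simplex_lattice,
)
from dietmix.reference import (
    reference_analysis,
    reference_criteria,
    reference_surfaces,
)
from dietmix.scheffe import fit, ladder_termset

CORNERS = [TESTED_BLENDS[1], TESTED_BLENDS[19], TESTED_BLENDS[15]]


def brute_force_lattice(step):
    """Independent enumeration of the lattice by exhaustive scanning."""
    lo, hi = STUDY_SPACE.lower_bounds, STUDY_SPACE.upper_bounds
    pts = []
    na = int(round((hi[0] - lo[0]) / step))
    nb = int(round((hi[1] - lo[1]) / step))
    for i, j in itertools.product(range(na + 1), range(nb + 1)):
        a = lo[0] + i * step
        b = lo[1] + j * step
        c = STUDY_SPACE.mixture_total - a - b
        if lo[2] - 1e-9 <= c <= hi[2] + 1e-9:
            pts.append((round(a, 6), round(b, 6), round(c, 6)))
    return sorted(pts)


class TestLattice:
    def test_coarse_lattice_matches_enumeration_oracle(self):
        # at step 1.5 the exhaustive oracle yields 6 feasible blends,
        # including all three corners
        oracle = brute_force_lattice(1.5)
        got = sorted(map(tuple, np.round(simplex_lattice(STUDY_SPACE, 1.5), 6)))
        assert got == oracle
        assert len(got) == 6
        for corner in CORNERS:
            assert tuple(np.round(corner, 6)) in got

    @pytest.mark.parametrize("step", [1.5, 0.5, 0.1])
    def test_lattice_blends_sum_to_mixture_total(self, step):
        lat = simplex_lattice(STUDY_SPACE, step)
        np.testing.assert_allclose(lat.sum(axis=1), STUDY_SPACE.mixture_total, atol=1e-9)
        assert len(lat) == len(brute_force_lattice(step))

    def test_bad_step_rejected(self):
        with pytest.raises(ValueError):
            simplex_lattice(STUDY_SPACE, 0.0)


class TestCriteria:
    def test_zero_variance_fit_gives_point_prediction_limit(self, noise_free_runs):
        surf = reference_surfaces()["duration_days"]
        mf = fit(noise_free_runs, "duration_days", surf.termset)
        crit = criteria_from_reference({"duration_days": mf})
        # sigma = 0: the CI collapses onto the prediction at the reference blend
        assert crit["duration_days"].limit == pytest.approx(
            float(mf.predict([CORNERS[0]])[0]), abs=1e-9
        )
        assert crit["duration_days"].bound_type == "maximum"

    def test_override_replaces_only_one_response(self, noisy_runs):
        fits = {
            "pupation": fit(noisy_runs, "pupation", ladder_termset("linear")),
            "duration_days": fit(noisy_runs, "duration_days", ladder_termset("linear")),
        }
        override = {"pupation": Criterion("pupation", "minimum", 0.5, source="user")}
        crit = criteria_from_reference(fits, overrides=override)
        assert crit["pupation"].limit == 0.5 and crit["pupation"].source == "user"
        base = criteria_from_reference(fits)
        assert crit["duration_days"].limit == base["duration_days"].limit

    def test_direction_determines_ci_endpoint(self, noisy_runs):
        mf = fit(noisy_runs, "pupation", ladder_termset("linear"))
        as_max = criteria_from_reference({"pupation": mf})["pupation"]
        as_min = criteria_from_reference(
            {"pupation": mf}, directions={"pupation": "minimize"}
        )["pupation"]
        assert as_max.bound_type == "minimum" and as_min.bound_type == "maximum"
        assert as_max.limit < as_min.limit  # lower vs upper CI endpoint


@pytest.fixture(scope="module")
def study_grid():
    return evaluate_grid(reference_surfaces(), study_cost_spec(), step=0.05)


class TestOperability:
    def test_impossible_criteria_flag_empty_region(self, study_grid):
        crit = {"pupation": Criterion("pupation", "minimum", 1.1)}
        result = operability_region(study_grid, crit)
        assert result.empty and len(result.feasible) == 0
        with pytest.raises(ValueError):
            max_savings_report(result, study_cost_spec())

    def test_vacuous_criteria_cover_whole_space(self, study_grid):
        crit = {"pupation": Criterion("pupation", "minimum", -1e9)}
        result = operability_region(study_grid, crit)
        assert len(result.feasible) == len(study_grid)
        # argmax = the cheapest vertex (all corn flour)
        assert result.argmax_blend == pytest.approx((3.0, 8.3, 19.0))

    def test_relaxing_a_criterion_never_shrinks_region(self, study_grid):
        crit = dict(reference_criteria())
        base = operability_region(study_grid, crit)
        relaxed = dict(crit)
        relaxed["duration_days"] = Criterion("duration_days", "maximum", 9.8)
        bigger = operability_region(study_grid, relaxed)
        assert len(bigger.feasible) >= len(base.feasible)
        base_set = set(map(tuple, base.feasible[["yeast_pct", "cornflour_pct"]].to_numpy()))
        big_set = set(map(tuple, bigger.feasible[["yeast_pct", "cornflour_pct"]].to_numpy()))
        assert base_set <= big_set

    def test_argmax_dominates_every_feasible_point(self, study_grid):
        result = operability_region(study_grid, reference_criteria())
        assert result.max_savings_percent == pytest.approx(
            result.feasible["savings_percent"].max()
        )
        assert (result.feasible["savings_percent"] <= result.max_savings_percent + 1e-12).all()

    def test_argmax_sits_on_duration_boundary_at_low_corncob(self, study_grid):
        result = operability_region(study_grid, reference_criteria())
        a = result.argmax_blend
        assert a[2] == pytest.approx(19.0)  # corncob at its floor
        dur = reference_surfaces()["duration_days"].predict([a])[0]
        assert 9.46 - 0.05 <= dur <= 9.46  # active duration constraint
        assert result.binding_constraints["duration_days"]

    def test_grid_refinement_stability(self):
        fits = reference_surfaces()
        spec = study_cost_spec()
        crit = reference_criteria()
        coarse = operability_region(evaluate_grid(fits, spec, step=0.04), crit)
        fine = operability_region(evaluate_grid(fits, spec, step=0.02), crit)
        for col in ("yeast_pct", "cornflour_pct", "corncob_pct"):
            lo_c, hi_c = coarse.component_ranges[col]
            lo_f, hi_f = fine.component_ranges[col]
            assert abs(lo_c - lo_f) <= 0.04 + 1e-9
            assert abs(hi_c - hi_f) <= 0.04 + 1e-9


class TestOverlay:
    def test_combined_mask_is_conjunction(self):
        grid = evaluate_grid(reference_surfaces(), study_cost_spec(), step=0.1)
        crit = reference_criteria()
        result = operability_region(grid, crit)
        ov = overlay_export(grid, crit, result)
        stacked = np.logical_and.reduce(list(ov["masks"].values()))
        np.testing.assert_array_equal(ov["combined"], stacked)
        assert ov["combined"].sum() == len(result.feasible)

    def test_duration_mask_is_most_restrictive(self):
        grid = evaluate_grid(reference_surfaces(), study_cost_spec(), step=0.1)
        crit = reference_criteria()
        ov = overlay_export(grid, crit, operability_region(grid, crit))
        areas = ov["mask_areas"]
        assert min(areas, key=areas.get) == "duration_days"

    def test_corner_grid_predictions_equal_linear_coefficients(self):
        surf = reference_surfaces()["pupation"]
        grid = evaluate_grid({"pupation": surf}, study_cost_spec(), step=1.5)
        for corner, coef in zip(CORNERS, surf.coef[:3]):
            row = grid.loc[
                (grid["yeast_pct"] == corner[0]) & (grid["cornflour_pct"] == corner[1])
            ]
            assert row["pupation"].iloc[0] == pytest.approx(coef, abs=1e-12)


class TestReferenceAnalysis:
    def test_component_ranges_and_savings(self):
        report = reference_analysis(step=0.02)
        region = report["_region_obj"]
        lo_y, _ = region.component_ranges["yeast_pct"]
        _, hi_f = region.component_ranges["cornflour_pct"]
        assert lo_y == pytest.approx(5.27, abs=0.02)
        assert hi_f == pytest.approx(6.03, abs=0.02)
        assert region.max_savings_percent >= 5.8  # coarse 0.02 lattice
        assert report["max_savings"]["savings_annual"] == pytest.approx(47_496, rel=0.02)
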