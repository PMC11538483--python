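"""Spot placement (IMPT + ELSA arc), minimax optimization, normalization."""

import itertools

import numpy as np
import pytest

import arcplan as ap
from arcplan.dose import Spot
from arcplan.planner import ObjectiveSet, ObjectiveTerm, _MinimaxProblem
from arcplan.robustness import ScenarioSpec
from arcplan.volumes import VoxelVolume


def make_structures(grid, **masks):
    ss = ap.StructureSet({name: grid.like(m) for name, m in masks.items()})
    return ss


@pytest.fixture(scope="module")
def water_grid():
    return VoxelVolume(np.ones((40, 40, 40)), (4.0, 4.0, 4.0))


class TestPlaceIMPT:
    def test_three_beam_plan_has_three_beams(self, small_setup):
        plan = ap.make_plan(small_setup, "IMPT")
        assert plan.modality == "IMPT"
        assert len(plan.beam_angles) == 3

    def test_point_like_target(self, water_grid):
        tgt = np.zeros(water_grid.shape, dtype=bool)
        tgt[20, 20, 20] = True
        ss = make_structures(water_grid, CTVexp=tgt)
        plan = ap.place_spots_impt(ss, [0.0, 90.0], density=water_grid, wepl_pad_mm=0.0)
        for ang in (0.0, 90.0):
            layers = [ly for ly in plan.layers if ly.angle_deg == ang]
            assert 1 <= len(layers) <= 2
            assert all(len(ly.spots) >= 1 for ly in layers)

    def test_slab_target_layer_count_matches_wepl_extent_oracle(self, water_grid):
        """Single-column slab target: the energy ladder matches an
        independent WEPL-extent calculation on the machine table."""
        tgt = np.zeros(water_grid.shape, dtype=bool)
        tgt[20, 15:26, 20] = True  # depths 60..100 mm in water
        ss = make_structures(water_grid, CTVexp=tgt)
        machine = ap.MachineModel(energy_ranges_mm=np.arange(40.0, 201.0, 5.0))
        pad = 3.0
        plan = ap.place_spots_impt(
            ss, [0.0], machine, density=water_grid, wepl_pad_mm=pad
        )
        # oracle: water -> WEPL == geometric depth from the grid entry face
        entry = -2.0  # bbox face, 2 mm before the first voxel center plane
        depths = (np.arange(15, 26) * 4.0) - entry
        lo, hi = depths.min() - pad, depths.max() + pad
        tab = machine.energy_ranges_mm
        expected = int(((tab >= lo) & (tab <= hi)).sum())
        assert len(plan.layers) == expected

    def test_unreachable_target_raises(self, water_grid):
        ss = make_structures(water_grid, CTVexp=np.zeros(water_grid.shape, dtype=bool))
        with pytest.raises(ValueError):
            ap.place_spots_impt(ss, [0.0], density=water_grid)


class TestPlaceELSA:
    def test_full_revolution_two_degree_spacing_yields_180_layers(self, small_setup):
        plan = ap.make_plan(small_setup, "PAT", arc_spacing_deg=2.0)
        assert plan.modality == "PAT"
        angles = [ly.angle_deg for ly in plan.layers]
        assert len(angles) <= 180
        assert len(angles) >= 170  # a few directions may be geometrically skipped
        assert len(set(angles)) == len(angles)  # exactly one EL per direction

    def test_one_energy_layer_per_direction(self, small_setup):
        plan = ap.make_plan(small_setup, "PAT", arc_spacing_deg=2.0)
        plan.validate()  # raises if any direction carries two layers

    def test_avoidance_sector_carries_no_spots(self, small_setup):
        plan = ap.make_plan(small_setup, "PAT", arc_spacing_deg=2.0, avoid_roi="Heart")
        ref = ap.make_plan(small_setup, "PAT", arc_spacing_deg=2.0)
        skipped = set(ly.angle_deg for ly in ref.layers) - set(
            ly.angle_deg for ly in plan.layers
        )
        assert len(skipped) > 0  # the heart blocks a sector of directions

    def test_spacing_outside_bounds_rejected_unless_overridden(self, small_setup):
        with pytest.raises(ValueError, match="spacing"):
            ap.make_plan(small_setup, "PAT", arc_spacing_deg=5.0)
        plan = ap.make_plan(
            small_setup, "PAT", arc_spacing_deg=5.0, allow_spacing_override=True
        )
        assert plan.angle_spacing_deg == 5.0

    def test_bounded_energy_step_between_adjacent_directions(self, small_setup):
        plan = ap.make_plan(small_setup, "PAT", arc_spacing_deg=2.0)
        machine = small_setup.machine
        idx = [machine.range_index(ly.range_mm) for ly in plan.layers]
        steps = np.abs(np.diff(idx))
        assert steps.max() <= 2


def toy_two_spot_problem():
    """2 spots, 2 scenarios, single-ROI objective on a water block."""
    grid = VoxelVolume(np.ones((24, 24, 24)), (4.0, 4.0, 4.0))
    tgt = np.zeros(grid.shape, dtype=bool)
    tgt[10:14, 10:14, 10:14] = True
    ss = ap.StructureSet({"CTVexp": grid.like(tgt)})
    iso = grid.index_to_world(np.array([11.5, 11.5, 11.5]))
    spots = [Spot(0.0, -4.0, 0.0, 50.0, 1.0), Spot(0.0, 4.0, 0.0, 50.0, 1.0)]
    layers = [ap.EnergyLayer(0.0, 50.0, spots)]
    plan = ap.TreatmentPlan("IMPT", layers, iso, ap.MachineModel(), prescription_gy=2.0)
    obj = ObjectiveSet(
        [
            ObjectiveTerm("CTVexp", "target_min", 2.0, 10.0, robust=True),
            ObjectiveTerm("CTVexp", "target_max", 2.2, 10.0, robust=True),
        ]
    )
    scenarios = [
        ScenarioSpec((0.0, 0.0, 0.0), 1.0, 0, is_nominal=True),
        ScenarioSpec((8.0, 0.0, 0.0), 1.0, 0),
    ]
    return grid, ss, plan, obj, scenarios


class TestMinimax:
    def test_single_scenario_reduces_to_plain_optimization(self):
        grid, ss, plan, obj, scenarios = toy_two_spot_problem()
        opt = ap.optimize_minimax(plan, obj, scenarios[:1], [grid], ss, max_iter=200)
        prob = _MinimaxProblem(plan, obj, scenarios[:1], [grid], ss)
        # with one scenario the worst case IS the nominal objective
        assert opt.diagnostics["objective_worst_case"] == pytest.approx(
            prob.nominal_value(opt.get_weights())
            + prob.scenario_values(opt.get_weights())[0]
        )

    def test_worst_case_at_least_nominal_objective(self):
        grid, ss, plan, obj, scenarios = toy_two_spot_problem()
        opt = ap.optimize_minimax(plan, obj, scenarios, [grid], ss, max_iter=200)
        prob = _MinimaxProblem(plan, obj, scenarios, [grid], ss)
        sv = prob.scenario_values(opt.get_weights())
        assert sv.max() >= sv[0] - 1e-12  # max over scenarios >= nominal member

    def test_two_spot_weights_match_brute_force_grid_search(self):
        """Optimizer lands on the exhaustive-grid minimax solution."""
        grid, ss, plan, obj, scenarios = toy_two_spot_problem()
        opt = ap.optimize_minimax(plan, obj, scenarios, [grid], ss, max_iter=400)
        prob = _MinimaxProblem(plan, obj, scenarios, [grid], ss)

        w_opt = opt.get_weights()
        f_opt = prob.exact_objective(w_opt)
        wmax = 3.0 * w_opt.max()
        grid_w = np.linspace(0.0, wmax, 200)
        best_f, best_w = np.inf, None
        for w1, w2 in itertools.product(grid_w, grid_w):
            f = prob.exact_objective(np.array([w1, w2]))
            if f < best_f:
                best_f, best_w = f, (w1, w2)
        step = grid_w[1] - grid_w[0]
        # the smoothed optimizer reaches the brute-force optimum up to the
        # log-sum-exp smoothing bias
        assert f_opt <= best_f * (1.0 + 1e-3)
        assert abs(w_opt[0] - best_w[0]) <= 2 * step
        assert abs(w_opt[1] - best_w[1]) <= 2 * step

    def test_minimax_monotone_in_scenario_set(self):
        """f*(S1) <= f*(S2) for nested scenario sets S1 within S2."""
        grid, ss, plan, obj, scenarios = toy_two_spot_problem()
        f_star = []
        for scen in (scenarios[:1], scenarios):
            opt = ap.optimize_minimax(plan, obj, scen, [grid], ss, max_iter=400)
            prob = _MinimaxProblem(plan, obj, scen, [grid], ss)
            f_star.append(prob.exact_objective(opt.get_weights()))
        assert f_star[0] <= f_star[1] + 1e-9

    def test_empty_scenario_list_rejected(self):
        grid, ss, plan, obj, _ = toy_two_spot_problem()
        with pytest.raises(ValueError):
            ap.optimize_minimax(plan, obj, [], [grid], ss)

    def test_weights_stay_nonnegative(self):
        grid, ss, plan, obj, scenarios = toy_two_spot_problem()
        opt = ap.optimize_minimax(plan, obj, scenarios, [grid], ss, max_iter=100)
        assert (opt.get_weights() >= 0).all()

    def test_pat_one_layer_per_direction_survives_optimization(self, small_setup):
        plan = ap.make_plan(
            small_setup, "PAT", arc_spacing_deg=12.0, allow_spacing_override=True
        )
        scen = ap.enumerate_scenarios(5.0, 0.0, [0])
        opt = ap.optimize_minimax(
            plan, ap.default_objectives(), scen, small_setup.phase_densities,
            small_setup.structures, max_iter=30, max_points_per_roi=800,
        )
        opt.validate(allow_spacing_override=True)


class TestNormalize:
    def test_d50_scaling_factor(self, small_setup, optimized_small_plan):
        dose = ap.compute_dose(optimized_small_plan, small_setup.phase_densities[0])
        half = optimized_small_plan.copy()
        half.set_weights(optimized_small_plan.get_weights() / 2.0)
        dose_half = ap.compute_dose(half, small_setup.phase_densities[0])
        renorm = ap.normalize_plan(half, dose_half, small_setup.structures["CTV"])
        assert renorm.diagnostics["normalization_scale"] == pytest.approx(2.0, rel=1e-9)

    def test_normalized_d50_equals_prescription(self, small_setup, optimized_small_plan):
        dose = ap.compute_dose(optimized_small_plan, small_setup.phase_densities[0])
        ctv = small_setup.structures["CTV"]
        curve = ap.DVHCurve.from_dose(dose, ctv)
        assert curve.d_percent(50.0) == pytest.approx(60.0, rel=1e-9)

    def test_d50_against_sort_based_percentile_oracle(self, small_setup, optimized_small_plan):
        dose = ap.compute_dose(optimized_small_plan, small_setup.phase_densities[0])
        ctv = small_setup.structures["CTV"].values.astype(bool)
        doses = np.sort(dose.values[ctv])
        oracle = float(np.quantile(doses, 0.5))
        curve = ap.DVHCurve.from_dose(dose, small_setup.structures["CTV"])
        assert curve.d_percent(50.0) == pytest.approx(oracle, rel=1e-12)

    def test_zero_dose_target_rejected(self, small_setup):
        plan = ap.make_plan(small_setup, "IMPT", lateral_spacing_mm=10.0)
        plan.set_weights(np.zeros(plan.n_spots))
        dose = ap.compute_dose(plan, small_setup.phases.midp)
        with pytest.raises(ValueError, match="zero dose"):
            ap.normalize_plan(plan, dose, small_setup.structures["CTV"])


class TestPlanIO:
    def test_json_roundtrip_preserves_plan(self, small_setup):
        plan = ap.make_plan(small_setup, "IMPT", lateral_spacing_mm=10.0)
        plan.set_weights(np.linspace(0.1, 2.0, plan.n_spots))
        text = plan.to_json()
        back = ap.TreatmentPlan.from_json(text)
        assert back.modality == plan.modality
        assert back.n_spots == plan.n_spots
        np.testing.assert_allclose(back.get_weights(), plan.get_weights())
        np.testing.assert_allclose(back.iso_mm, plan.iso_mm)
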