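"""Timing/BDT models, spot-to-phase distribution, 4DDD accumulation, bands."""

import numpy as np
import pytest

import arcplan as ap
from arcplan.dose import Spot, iter_spots
from arcplan.interplay import TimingConfig, TimingSchedule, distribute_spots_to_phases


def impt_two_layer_plan():
    """2-layer, 3-spot single-beam IMPT plan with hand-checkable timing."""
    s1 = [Spot(0.0, 0.0, 0.0, 100.0, 10.0), Spot(0.0, 5.0, 0.0, 100.0, 20.0)]
    s2 = [Spot(0.0, 0.0, 0.0, 95.0, 5.0)]
    layers = [ap.EnergyLayer(0.0, 100.0, s1), ap.EnergyLayer(0.0, 95.0, s2)]
    return ap.TreatmentPlan("IMPT", layers, np.zeros(3), ap.MachineModel())


class TestTiming:
    def test_empty_plan_zero_bdt(self):
        plan = ap.TreatmentPlan("IMPT", [], np.zeros(3), ap.MachineModel())
        sched = ap.simulate_timing(plan)
        assert sched.total_bdt_s == 0.0

    def test_hand_summed_impt_schedule(self):
        """Spot dwell + spot switch + energy switch, summed by hand."""
        tc = TimingConfig(spot_switch_s=0.1, mu_rate_per_s=10.0,
                          energy_down_switch_s=0.6, energy_up_switch_s=5.0)
        sched = ap.simulate_timing(impt_two_layer_plan(), tc)
        # layer 1: spot(1.0 s) + switch(0.1) + spot(2.0); energy down 0.6; spot(0.5)
        expect_times = [0.0, 1.1, 1.1 + 2.0 + 0.6]
        np.testing.assert_allclose(sched.spot_times_s, expect_times)
        assert sched.total_bdt_s == pytest.approx(3.7 + 0.5)
        assert sched.layer_switch_intervals == [(3.1, 3.7)]

    def test_impt_inter_beam_travel_positive(self, small_setup):
        plan = ap.make_plan(small_setup, "IMPT", lateral_spacing_mm=10.0)
        plan.set_weights(np.ones(plan.n_spots))
        sched = ap.simulate_timing(plan)
        assert len(plan.beam_angles) >= 2
        assert sched.inter_beam_travel_s > 0.0

    def test_pat_inter_beam_travel_is_zero(self, small_setup):
        plan = ap.make_plan(
            small_setup, "PAT", arc_spacing_deg=6.0, allow_spacing_override=True
        )
        plan.set_weights(np.ones(plan.n_spots))
        sched = ap.simulate_timing(plan)
        assert sched.inter_beam_travel_s == 0.0
        assert sched.beam_travel_intervals == []

    def test_pat_rotation_respects_gantry_speed(self, small_setup):
        plan = ap.make_plan(
            small_setup, "PAT", arc_spacing_deg=6.0, allow_spacing_override=True
        )
        plan.set_weights(np.full(plan.n_spots, 0.1))
        tc = TimingConfig(gantry_speed_deg_s=6.0)
        sched = ap.simulate_timing(plan, tc)
        g = sched.gantry_angle_vs_time
        dt = np.diff(g[:, 0])
        dang = np.array([min(abs(d), 360 - abs(d)) for d in np.diff(g[:, 1])])
        # arrival intervals can never beat the speed limit
        assert np.all(dang <= 6.0 * dt + 1e-9)

    def test_times_nondecreasing_invariant(self):
        with pytest.raises(ValueError):
            TimingSchedule(np.array([1.0, 0.5]), [], [], None, 1.0)


class TestDistribution:
    def _sched(self, times):
        return TimingSchedule(np.asarray(times, dtype=float), [], [], None,
                              float(times[-1]) if len(times) else 0.0)

    def test_fast_delivery_stays_in_starting_phase(self):
        sched = self._sched([0.0, 0.05, 0.1])  # all within period/P = 0.4 s
        out = distribute_spots_to_phases(sched, 4.0, 10, start_phase=3)
        assert out[3] == [0, 1, 2]
        assert all(not out[p] for p in range(10) if p != 3)

    def test_start_phase_sweep_gives_ten_distinct_scenarios(self):
        rng = np.random.default_rng(4)
        sched = self._sched(np.sort(rng.uniform(0, 12, 40)))
        seen = set()
        for k in range(10):
            out = distribute_spots_to_phases(sched, 4.0, 10, k)
            seen.add(tuple(tuple(p) for p in out))
        assert len(seen) == 10

    def test_matches_per_spot_modular_oracle(self):
        rng = np.random.default_rng(6)
        times = np.sort(rng.uniform(0, 30, 100))
        sched = self._sched(times)
        P, T, k = 10, 4.0, 7
        out = distribute_spots_to_phases(sched, T, P, k)
        for i, t in enumerate(times):
            oracle = (int(np.floor((t % T) / T * P)) + k) % P
            assert i in out[oracle]

    def test_every_spot_assigned_exactly_once(self):
        sched = self._sched(np.linspace(0, 9.7, 57))
        out = distribute_spots_to_phases(sched, 4.0, 10, 0)
        flat = sorted(i for lst in out for i in lst)
        assert flat == list(range(57))

    def test_start_phase_out_of_range(self):
        with pytest.raises(ValueError):
            distribute_spots_to_phases(self._sched([0.0]), 4.0, 10, 10)


class TestAccumulation:
    def test_zero_amplitude_accumulation_equals_static_dose(self, small_cfg):
        cfg = ap.PhantomConfig(**{**small_cfg.__dict__, "amplitude_mm": 0.0})
        setup = ap.default_setup(cfg)
        plan = ap.make_plan(setup, "IMPT", lateral_spacing_mm=10.0)
        plan.set_weights(np.ones(plan.n_spots))
        sched = ap.simulate_timing(plan)
        assign = distribute_spots_to_phases(sched, 4.0, setup.phases.n_phases, 0)
        scen = ap.accumulate_4ddd(plan, setup.phases, assign, "0")
        static = ap.compute_dose(plan, setup.phases.midp)
        np.testing.assert_allclose(
            scen.accumulated.values, static.values, rtol=1e-9, atol=1e-12
        )

    def test_all_spots_in_one_phase_equals_warped_single_phase_dose(self, small_phantom):
        p4d, ss = small_phantom
        from arcplan.phantom import warp_to_midp

        spot = Spot(0.0, 0.0, 0.0, 80.0, 1.0)
        layers = [ap.EnergyLayer(0.0, 80.0, [spot])]
        iso = p4d.midp_center_mm
        plan = ap.TreatmentPlan("IMPT", layers, iso, ap.MachineModel())
        assign = [[] for _ in range(p4d.n_phases)]
        assign[2] = [0]
        scen = ap.accumulate_4ddd(plan, p4d, assign, "x")
        oracle = warp_to_midp(
            ap.compute_dose(plan, p4d.phases[2]).volume, p4d.dvf_to_midp[2]
        )
        np.testing.assert_allclose(scen.accumulated.values, oracle.values, atol=1e-12)

    def test_dose_conservation_under_identity_dvfs(self, small_cfg):
        """Partial doses sum to the full static dose voxel-wise when every
        DVF is the identity (zero amplitude)."""
        cfg = ap.PhantomConfig(**{**small_cfg.__dict__, "amplitude_mm": 0.0})
        p4d, ss = ap.build_phantom(cfg)
        setup = ap.default_setup(cfg)
        plan = ap.make_plan(setup, "IMPT", lateral_spacing_mm=10.0)
        plan.set_weights(np.linspace(0.5, 1.5, plan.n_spots))
        sched = ap.simulate_timing(plan)
        assign = distribute_spots_to_phases(sched, 4.0, p4d.n_phases, 1)
        scen = ap.accumulate_4ddd(plan, setup.phases, assign, "1")
        static = ap.compute_dose(plan, setup.phases.midp)
        err = np.abs(scen.accumulated.values - static.values)
        assert err.max() <= 1e-9 * static.values.max()

    def test_rigid_translation_shifted_kernel_oracle(self, small_phantom):
        """Grid-snapped rigid motion: inside the motion envelope the warped
        partial dose equals the phase dose rolled by the phase offset."""
        p4d, ss = small_phantom
        from arcplan.phantom import warp_to_midp

        p = 2
        dz_mm = p4d.midp_center_mm[2] - p4d.gtv_centers_mm[p, 2]
        vox = int(round(dz_mm / p4d.phases[p].spacing[2]))
        spot = Spot(90.0, 0.0, 0.0, 60.0, 1.0)
        plan = ap.TreatmentPlan(
            "IMPT", [ap.EnergyLayer(90.0, 60.0, [spot])],
            p4d.gtv_centers_mm[p], ap.MachineModel(),
        )
        dose_p = ap.compute_dose(plan, p4d.phases[p])
        warped = warp_to_midp(dose_p.volume, p4d.dvf_to_midp[p])
        rolled = np.roll(dose_p.values, vox, axis=2)
        ctv = ss.mask("CTV")
        np.testing.assert_allclose(
            warped.values[ctv], rolled[ctv], rtol=1e-9, atol=1e-12
        )


class TestBands:
    def test_zero_amplitude_bandwidths_exactly_zero(self, small_cfg):
        cfg = ap.PhantomConfig(**{**small_cfg.__dict__, "amplitude_mm": 0.0})
        setup = ap.default_setup(cfg)
        plan = ap.make_plan(setup, "IMPT", lateral_spacing_mm=10.0)
        plan.set_weights(np.ones(plan.n_spots))
        band, scens = ap.interplay_bands(plan, setup.phases, setup.structures)
        assert band.bandwidth["D98%"] == 0.0
        assert band.bandwidth["D1%"] == 0.0

    def test_ten_start_phases_ten_scenarios(self, small_cfg):
        cfg = ap.PhantomConfig(**{**small_cfg.__dict__, "n_phases": 10})
        setup = ap.default_setup(cfg)
        plan = ap.make_plan(setup, "IMPT", lateral_spacing_mm=10.0)
        plan.set_weights(np.ones(plan.n_spots))
        band, scens = ap.interplay_bands(plan, setup.phases, setup.structures)
        assert len(scens) == 10
        assert len(band.per_scenario["D98%"]) == 10
        assert band.bandwidth["D98%"] >= 0.0

    def test_two_phase_band_equals_direct_recomputation(self, small_cfg):
        """Two starting phases: the band is |value(0) - value(1)| computed
        by running the two 4DDD simulations directly."""
        cfg = ap.PhantomConfig(**{**small_cfg.__dict__, "n_phases": 2})
        setup = ap.default_setup(cfg)
        plan = ap.make_plan(setup, "IMPT", lateral_spacing_mm=10.0)
        plan.set_weights(np.ones(plan.n_spots))
        band, _ = ap.interplay_bands(plan, setup.phases, setup.structures)

        sched = ap.simulate_timing(plan)
        vals = []
        for k in (0, 1):
            assign = distribute_spots_to_phases(sched, setup.phases.period_s, 2, k)
            scen = ap.accumulate_4ddd(plan, setup.phases, assign, str(k))
            curve = ap.DVHCurve.from_dose(scen.accumulated, setup.structures["CTV"])
            vals.append(curve.d_percent(98.0))
        assert band.bandwidth["D98%"] == pytest.approx(abs(vals[0] - vals[1]), rel=1e-12)

    def test_band_contains_static_value_for_slow_breathing(self, small_cfg):
        """As the period grows far beyond the delivery time, every scenario
        approaches its single-start-phase accumulated dose."""
        setup = ap.default_setup(small_cfg)
        plan = ap.make_plan(setup, "IMPT", lateral_spacing_mm=10.0)
        plan.set_weights(np.ones(plan.n_spots))
        sched = ap.simulate_timing(plan)
        long_period = 1e6
        assign = distribute_spots_to_phases(
            sched, long_period, setup.phases.n_phases, 0
        )
        # all spots land in the starting phase
        assert len(assign[0]) == plan.n_spots
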