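"""4D dynamic dose (interplay) simulation and beam-delivery-time models.

The interplay pipeline follows the standard 4D dynamic dose (4DDD) recipe:
(1) simulate the delivery time of every spot from a machine timing model;
(2) distribute spots over breathing phases according to those times, a
breathing period and a starting phase; (3) compute the partial dose of
each phase's spots on that phase's density; (4) warp every partial dose to
the MidP reference with the phase's exact DVF and sum.  Repeating the
simulation once per starting phase (10 for a 10-phase series) yields the
interplay scenario set, summarized by DVH-band statistics (max - min of
CTV D98% and D1% across scenarios; the narrower the band, the more robust
the plan).

Beam delivery time (BDT): IMPT uses a start-and-stop trajectory — spots
and energy switches in sequence per beam, plus gantry/couch travel between
beams.  PAT delivers one continuous revolution whose angular velocity is
capped by the gantry speed limit and which cannot arrive at a direction
before its energy switch completes; inter-beam travel is identically zero
for an arc.  The timing constants are surrogate machine parameters,
configurable via YAML.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .dose import DoseDistribution, compute_dose, iter_spots
from .phantom import Phase4DSet, warp_to_midp
from .volumes import VoxelVolume

__all__ = [
    "TimingConfig",
    "TimingSchedule",
    "simulate_timing",
    "distribute_spots_to_phases",
    "InterplayScenario",
    "accumulate_4ddd",
    "DVHBand",
    "interplay_bands",
]


@dataclass
class TimingConfig:
    """Surrogate delivery timing constants (all seconds unless noted)."""

    #: lateral scanning-magnet move between successive spots
    spot_switch_s: float = 0.002
    #: weight units delivered per second (spot dwell = weight / rate)
    mu_rate_per_s: float = 50.0
    #: energy switch to a lower / higher energy layer
    energy_down_switch_s: float = 0.6
    energy_up_switch_s: float = 5.0
    #: gantry rotation speed limit, deg/s
    gantry_speed_deg_s: float = 6.0
    #: fixed per-gap overhead for IMPT beam changes (couch, checks)
    inter_beam_overhead_s: float = 20.0

    @classmethod
    def from_yaml(cls, path: str) -> "TimingConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


@dataclass
class TimingSchedule:
    """Absolute delivery start time per spot plus overhead bookkeeping."""

    spot_times_s: np.ndarray  # one entry per plan spot, plan order
    layer_switch_intervals: list[tuple[float, float]]
    beam_travel_intervals: list[tuple[float, float]]  # IMPT only; empty for PAT
    gantry_angle_vs_time: np.ndarray | None  # (t, angle) samples, PAT only
    total_bdt_s: float

    def __post_init__(self) -> None:
        t = np.asarray(self.spot_times_s, dtype=float)
        if t.size and np.any(np.diff(t) < -1e-12):
            raise ValueError("spot times must be nondecreasing")
        self.spot_times_s = t

    @property
    def inter_beam_travel_s(self) -> float:
        return float(sum(b - a for a, b in self.beam_travel_intervals))


def _angle_gap_deg(a: float, b: float) -> float:
    d = abs(b - a) % 360.0
    return min(d, 360.0 - d)


def simulate_timing(plan, timing: TimingConfig | None = None) -> TimingSchedule:
    """Delivery schedule and total BDT for an IMPT or PAT plan."""
    timing = timing or TimingConfig()
    layers = plan.layers
    if not layers or all(len(ly.spots) == 0 for ly in layers):
        return TimingSchedule(np.empty(0), [], [], None, 0.0)

    spot_times: list[float] = []
    switch_iv: list[tuple[float, float]] = []
    travel_iv: list[tuple[float, float]] = []
    gantry_samples: list[tuple[float, float]] = []
    t = 0.0
    prev_angle: float | None = None
    prev_range: float | None = None

    for ly in layers:
        if prev_angle is not None:
            if plan.modality == "IMPT" and abs(ly.angle_deg - prev_angle) > 1e-9:
                # beam change: gantry/couch travel plus fixed overhead
                travel = (
                    _angle_gap_deg(prev_angle, ly.angle_deg) / timing.gantry_speed_deg_s
                    + timing.inter_beam_overhead_s
                )
                travel_iv.append((t, t + travel))
                t += travel
                prev_range = None  # energy sequence restarts per beam
            elif plan.modality == "PAT":
                rot = _angle_gap_deg(prev_angle, ly.angle_deg) / timing.gantry_speed_deg_s
                ready = t
                if prev_range is not None and abs(ly.range_mm - prev_range) > 1e-9:
                    sw = (
                        timing.energy_down_switch_s
                        if ly.range_mm < prev_range
                        else timing.energy_up_switch_s
                    )
                    switch_iv.append((t, t + sw))
                    ready = t + sw
                # arrive no earlier than rotation allows, no earlier than ready
                t = max(t + rot, ready)
        if plan.modality == "IMPT" and prev_range is not None and prev_angle == ly.angle_deg:
            sw = (
                timing.energy_down_switch_s
                if ly.range_mm < prev_range
                else timing.energy_up_switch_s
            )
            switch_iv.append((t, t + sw))
            t += sw

        if plan.modality == "PAT":
            gantry_samples.append((t, ly.angle_deg))
        for k, s in enumerate(ly.spots):
            if k > 0:
                t += timing.spot_switch_s
            spot_times.append(t)
            t += s.weight / timing.mu_rate_per_s
        prev_angle = ly.angle_deg
        prev_range = ly.range_mm

    return TimingSchedule(
        np.asarray(spot_times),
        switch_iv,
        travel_iv,
        np.asarray(gantry_samples) if gantry_samples else None,
        total_bdt_s=t,
    )


def distribute_spots_to_phases(
    schedule: TimingSchedule, period_s: float, n_phases: int, start_phase: int
) -> list[list[int]]:
    """Assign each spot (by plan index) to the breathing phase it lands in.

    Phase dwell times are uniform (period / P); the spot delivered at time
    t belongs to phase floor(((t mod T) / T) * P + start_phase) mod P.
    Spots are instantaneous at their start time.
    """
    if period_s <= 0:
        raise ValueError("period must be > 0")
    if not (0 <= start_phase < n_phases):
        raise ValueError("start_phase out of range")
    out: list[list[int]] = [[] for _ in range(n_phases)]
    t = schedule.spot_times_s
    ph = (np.floor((t % period_s) / period_s * n_phases) + start_phase).astype(int) % n_phases
    for i, p in enumerate(ph):
        out[p].append(i)
    return out


@dataclass
class InterplayScenario:
    """One 4DDD simulation: per-phase partial doses and the MidP sum."""

    start_phase: int
    partial_doses: list[DoseDistribution | None]  # per phase, None = no spots
    accumulated: DoseDistribution


def accumulate_4ddd(
    plan,
    phases: Phase4DSet,
    assignment: list[list[int]],
    scenario_id: str = "",
    *,
    mass_weighted: bool = False,
) -> InterplayScenario:
    """Partial-dose computation per phase, exact-DVF warp to MidP, and sum.

    ``mass_weighted=True`` switches the warp to the energy-conserving
    variant (dose x density pulled back, then divided by the MidP
    density); the plain dose pull-back is the default.
    """
    if len(assignment) != phases.n_phases:
        raise ValueError("assignment must have one spot list per phase")
    spots = iter_spots(plan)
    acc = np.zeros(phases.midp.shape)
    partials: list[DoseDistribution | None] = []
    for p, idxs in enumerate(assignment):
        if not idxs:
            partials.append(None)
            continue
        sub = [spots[i] for i in idxs]
        partial = compute_dose(
            plan, phases.phases[p], spots=sub, provenance=f"{scenario_id}/phase{p}"
        )
        partials.append(partial)
        dvf = phases.dvf_to_midp[p]
        if mass_weighted:
            rho_p = phases.phases[p]
            num = warp_to_midp(rho_p.like(partial.values * rho_p.values), dvf).values
            den = np.maximum(phases.midp.values, 1e-6)
            acc += num / den
        else:
            acc += warp_to_midp(partial.volume, dvf).values
    accumulated = DoseDistribution(
        phases.midp.like(np.maximum(acc, 0.0)), provenance=f"4DDD[{scenario_id}]"
    )
    return InterplayScenario(int(scenario_id) if scenario_id.isdigit() else -1, partials, accumulated)


@dataclass
class DVHBand:
    """Min/max/bandwidth of DVH metrics over the interplay scenario set."""

    roi: str
    per_scenario: dict[str, np.ndarray]  # metric -> value per starting phase
    minimum: dict[str, float] = field(default_factory=dict)
    maximum: dict[str, float] = field(default_factory=dict)
    bandwidth: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for m, vals in self.per_scenario.items():
            vals = np.asarray(vals, dtype=float)
            self.per_scenario[m] = vals
            self.minimum[m] = float(vals.min())
            self.maximum[m] = float(vals.max())
            self.bandwidth[m] = float(vals.max() - vals.min())


def interplay_bands(
    plan,
    phases: Phase4DSet,
    structures,
    *,
    period_s: float | None = None,
    start_phases: list[int] | None = None,
    roi: str = "CTV",
    metrics: tuple[str, ...] = ("D98%", "D1%"),
    timing: TimingConfig | None = None,
    mass_weighted: bool = False,
) -> tuple[DVHBand, list[InterplayScenario]]:
    """Full interplay analysis: one 4DDD simulation per starting phase.

    Exploits the structure of the phase assignment: shifting the starting
    phase by k rotates every spot's phase by k, so the partial dose of
    (spot bin g, phase p) can be computed once and reused across
    scenarios.
    """
    from .evaluation import DVHCurve

    period = period_s if period_s is not None else phases.period_s
    P = phases.n_phases
    starts = list(start_phases) if start_phases is not None else list(range(P))
    schedule = simulate_timing(plan, timing)
    spots = iter_spots(plan)
    if len(schedule.spot_times_s) != len(spots):
        raise ValueError("schedule does not match the plan's spots")

    base = distribute_spots_to_phases(schedule, period, P, 0)

    # cache: (bin g, phase p) -> warped partial dose on MidP
    warped: dict[tuple[int, int], np.ndarray] = {}
    partial_cache: dict[tuple[int, int], DoseDistribution | None] = {}

    def warped_partial(g: int, p: int) -> tuple[np.ndarray | None, DoseDistribution | None]:
        key = (g, p)
        if key not in warped:
            idxs = base[g]
            if not idxs:
                warped[key] = None  # type: ignore[assignment]
                partial_cache[key] = None
            else:
                sub = [spots[i] for i in idxs]
                partial = compute_dose(
                    plan, phases.phases[p], spots=sub, provenance=f"bin{g}/phase{p}"
                )
                partial_cache[key] = partial
                dvf = phases.dvf_to_midp[p]
                if mass_weighted:
                    rho_p = phases.phases[p]
                    num = warp_to_midp(rho_p.like(partial.values * rho_p.values), dvf).values
                    w = num / np.maximum(phases.midp.values, 1e-6)
                else:
                    w = warp_to_midp(partial.volume, dvf).values
                warped[key] = w
        return warped[key], partial_cache[key]

    scenarios: list[InterplayScenario] = []
    values: dict[str, list[float]] = {m: [] for m in metrics}
    mask = structures[roi]
    for k in starts:
        acc = np.zeros(phases.midp.shape)
        partials: list[DoseDistribution | None] = [None] * P
        # accumulate in bin order (not phase order) so scenarios that share
        # the same addends sum them identically, bit for bit
        for g in range(P):
            p = (g + k) % P
            w, partial = warped_partial(g, p)
            if w is not None:
                acc += w
                partials[p] = partial
        accumulated = DoseDistribution(
            phases.midp.like(np.maximum(acc, 0.0)), provenance=f"4DDD[start={k}]"
        )
        scenarios.append(InterplayScenario(k, partials, accumulated))
        curve = DVHCurve.from_dose(accumulated, mask, roi_name=roi)
        for m in metrics:
            values[m].append(curve.metric(m))

    band = DVHBand(roi, {m: np.asarray(v) for m, v in values.items()})
    return band, scenarios
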