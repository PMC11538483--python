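"""End-to-end convenience drivers: phantom -> plan -> optimize -> normalize.

These wrappers wire the individual modules together with the study's
default conditions (5 mm optimizer setup error after margin splitting,
+/-3% range error, D50% = 60 Gy normalization) so examples, tests and the
acceptance script share one code path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bragg import MachineModel
from .dose import compute_dose
from .phantom import PhantomConfig, Phase4DSet, StructureSet, build_phantom
from .planner import (
    ObjectiveSet,
    TreatmentPlan,
    default_objectives,
    normalize_plan,
    optimize_minimax,
    place_spots_impt,
    place_spots_pat_elsa,
)
from .robustness import ScenarioSpec, enumerate_scenarios, select_phase_densities
from .structures import MarginSpec, expand_anisotropic, split_margin

__all__ = ["PlanningSetup", "prepare_structures", "make_plan", "optimize_and_normalize"]

DEFAULT_TOTAL_MARGIN_MM = 8.0
DEFAULT_OPTIMIZER_SETUP_MM = 5.0
DEFAULT_RANGE_ERROR = 0.03


@dataclass
class PlanningSetup:
    """A phantom with planning structures and scenario machinery attached."""

    phases: Phase4DSet
    structures: StructureSet
    machine: MachineModel
    optimizer_setup_mm: float
    range_error: float
    phase_densities: list  # densities indexed by ScenarioSpec.phase
    scenarios: list[ScenarioSpec]


def prepare_structures(
    phases: Phase4DSet,
    structures: StructureSet,
    total_margin: MarginSpec | None = None,
    optimizer_part_mm: float = DEFAULT_OPTIMIZER_SETUP_MM,
) -> tuple[StructureSet, float]:
    """Split the total setup margin and add the CTVexp expansion ROI."""
    total = total_margin or MarginSpec.isotropic(DEFAULT_TOTAL_MARGIN_MM)
    geometric, setup_mm = split_margin(total, optimizer_part_mm)
    if max(geometric.as_tuple()) > 0:
        ctv_exp = expand_anisotropic(structures["CTV"], geometric)
    else:
        ctv_exp = structures["CTV"]
    structures.add("CTVexp", ctv_exp)
    return structures, setup_mm


def default_setup(
    cfg: PhantomConfig | None = None,
    *,
    machine: MachineModel | None = None,
    opt_phases: tuple[str, ...] = ("midp", "end_exhale", "end_inhale", "mid_vent"),
    range_error: float = DEFAULT_RANGE_ERROR,
) -> PlanningSetup:
    """Build the default phantom and its 84-scenario optimization grid."""
    phases, structures = build_phantom(cfg)
    structures, setup_mm = prepare_structures(phases, structures)
    machine = machine or MachineModel()
    densities = select_phase_densities(phases, opt_phases)
    scenarios = enumerate_scenarios(setup_mm, range_error, list(range(len(densities))))
    return PlanningSetup(
        phases, structures, machine, setup_mm, range_error, densities, scenarios
    )


def make_plan(
    setup: PlanningSetup,
    modality: str = "IMPT",
    *,
    beams: list[float] = (350.0, 45.0, 170.0),
    arc_spacing_deg: float = 2.0,
    lateral_spacing_mm: float = 8.0,
    allow_spacing_override: bool = False,
    avoid_roi: str | None = None,
) -> TreatmentPlan:
    """Geometric spot placement for either modality on the MidP image."""
    midp = setup.phases.midp
    if modality == "IMPT":
        return place_spots_impt(
            setup.structures,
            list(beams),
            setup.machine,
            density=midp,
            lateral_spacing_mm=lateral_spacing_mm,
        )
    if modality == "PAT":
        return place_spots_pat_elsa(
            setup.structures,
            {"spacing_deg": arc_spacing_deg},
            setup.machine,
            density=midp,
            lateral_spacing_mm=lateral_spacing_mm,
            avoid_roi=avoid_roi,
            allow_spacing_override=allow_spacing_override,
        )
    raise ValueError(f"unknown modality {modality!r}")


def optimize_and_normalize(
    setup: PlanningSetup,
    plan: TreatmentPlan,
    objectives: ObjectiveSet | None = None,
    *,
    scenarios: list[ScenarioSpec] | None = None,
    max_iter: int = 80,
    max_points_per_roi: int = 3000,
    seed: int = 0,
) -> TreatmentPlan:
    """Minimax-optimize spot weights, then normalize CTV D50% to prescription."""
    objectives = objectives or default_objectives(plan.prescription_gy)
    scen = scenarios if scenarios is not None else setup.scenarios
    opt = optimize_minimax(
        plan,
        objectives,
        scen,
        setup.phase_densities,
        setup.structures,
        max_iter=max_iter,
        max_points_per_roi=max_points_per_roi,
        seed=seed,
    )
    nominal = next((s for s in scen if s.is_nominal), scen[0])
    dose = compute_dose(opt, setup.phase_densities[nominal.phase], provenance="nominal")
    return normalize_plan(opt, dose, setup.structures["CTV"], 50.0, plan.prescription_gy)
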