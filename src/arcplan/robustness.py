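"""Scenario enumeration and worst-case robustness evaluation.

The scenario grid is the standard minimax product: setup shifts (six
axis-aligned directions of a given magnitude plus the nominal position) x
range scalings {1 - rho, 1, 1 + rho} x breathing phases.  With a 5 mm setup
error, a 3% range error and four phases this yields the study's 84-scenario
grid.  Worst-case metrics are composite per metric: each clinical goal's
worst value is taken over all scenarios independently (min over scenarios
for >=-type coverage goals, max for <-type sparing goals).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .dose import compute_dose
from .evaluation import DVHCurve
from .phantom import Phase4DSet, StructureSet
from .volumes import VoxelVolume

__all__ = [
    "ScenarioSpec",
    "enumerate_scenarios",
    "select_phase_densities",
    "evaluate_scenarios",
    "ClinicalGoal",
    "default_clinical_goals",
    "worst_case_metrics",
]

_AXIS_DIRECTIONS = np.array(
    [
        [1, 0, 0], [-1, 0, 0],
        [0, 1, 0], [0, -1, 0],
        [0, 0, 1], [0, 0, -1],
    ],
    dtype=float,
)


@dataclass(frozen=True)
class ScenarioSpec:
    """One (setup shift, range scale, phase) triple of the robustness grid."""

    setup_shift_mm: tuple[float, float, float]
    range_scale: float
    phase: int  # index into the phase-density list in use
    is_nominal: bool = False

    def __post_init__(self) -> None:
        if self.range_scale <= 0:
            raise ValueError("range_scale must be > 0")


def enumerate_scenarios(
    setup_mm: float,
    range_pct: float,
    phases: list[int],
    *,
    per_direction_mm: dict[int, tuple[float, float]] | None = None,
) -> list[ScenarioSpec]:
    """Full setup x range x phase scenario grid.

    Parameters
    ----------
    setup_mm : float
        Setup-error magnitude; > 0 adds the six axis-aligned shifted
        scenarios on top of the unshifted one.
    range_pct : float
        Fractional range error rho; > 0 adds scales 1 - rho and 1 + rho.
    phases : list of int
        Phase indices (into whatever density list the evaluation uses).
    per_direction_mm : optional
        Anisotropic override: axis -> (+magnitude, -magnitude) in mm, used
        when the evaluation setup error equals a non-isotropic margin.

    With setup 5 mm, range 3% and four phases this returns the
    (1 + 6) x 3 x 4 = 84 scenario grid.
    """
    if setup_mm < 0:
        raise ValueError("setup_mm must be >= 0")
    if not (0 <= range_pct < 1):
        raise ValueError("range_pct must be in [0, 1)")
    if len(phases) == 0:
        raise ValueError("need at least one phase")

    shifts: list[np.ndarray] = [np.zeros(3)]
    if setup_mm > 0 or per_direction_mm:
        for d in _AXIS_DIRECTIONS:
            axis = int(np.argmax(np.abs(d)))
            mag = setup_mm
            if per_direction_mm and axis in per_direction_mm:
                plus, minus = per_direction_mm[axis]
                mag = plus if d[axis] > 0 else minus
            if mag > 0:
                shifts.append(d * mag)
    scales = [1.0]
    if range_pct > 0:
        scales = [1.0 - range_pct, 1.0, 1.0 + range_pct]

    ref_phase = phases[0]
    out: list[ScenarioSpec] = []
    for ph in phases:
        for sc in scales:
            for sh in shifts:
                nominal = bool(np.all(sh == 0) and sc == 1.0 and ph == ref_phase)
                out.append(ScenarioSpec(tuple(sh), sc, ph, is_nominal=nominal))
    return out


def select_phase_densities(
    p4d: Phase4DSet, which: tuple[str, ...] = ("midp", "end_exhale", "end_inhale", "mid_vent")
) -> list[VoxelVolume]:
    """Pick the evaluation/optimization densities from a 4D set.

    'midp' is the reconstruction reference; end-exhale is phase 0 of the
    1-cos trajectory, end-inhale the half-period phase, mid-ventilation the
    quarter-period phase.
    """
    P = p4d.n_phases
    lut = {
        "midp": lambda: p4d.midp,
        "end_exhale": lambda: p4d.phases[0],
        "end_inhale": lambda: p4d.phases[P // 2],
        "mid_vent": lambda: p4d.phases[P // 4],
    }
    out = []
    for name in which:
        if name not in lut:
            raise ValueError(f"unknown phase selector {name!r}")
        out.append(lut[name]())
    return out


def evaluate_scenarios(
    plan,
    scenarios: list[ScenarioSpec],
    phase_densities: list[VoxelVolume],
    structures: StructureSet,
    eval_rois: list[str] = ("CTV",),
) -> dict[tuple[int, str], DVHCurve]:
    """One DVH curve per (scenario index, ROI) under the scenario's dose.

    Evaluation deliberately uses the *raw* CTV (not the optimization
    expansion) by default, mirroring how robustness is judged clinically.
    """
    for roi in eval_rois:
        if roi not in structures:
            raise ValueError(f"missing ROI {roi!r}")
    out: dict[tuple[int, str], DVHCurve] = {}
    for i, sc in enumerate(scenarios):
        dose = compute_dose(
            plan,
            phase_densities[sc.phase],
            sc.setup_shift_mm,
            sc.range_scale,
            provenance=f"scenario[{i}]",
        )
        for roi in eval_rois:
            out[(i, roi)] = DVHCurve.from_dose(dose, structures[roi], roi_name=roi)
    return out


# ---------------------------------------------------------------------------
# clinical goals


@dataclass(frozen=True)
class ClinicalGoal:
    """One row of the clinical-goal table.

    metric syntax: 'D98%', 'D95%', 'D1%', 'D0.04cc', 'D1cc', 'Dmean',
    'V30Gy'.  sense '>=' means a coverage goal (worst = min over
    scenarios); '<' a sparing goal (worst = max).  scope 'nominal' goals
    are checked on the nominal scenario only; 'worst' goals over the grid.
    """

    roi: str
    metric: str
    sense: str
    limit: float
    scope: str = "nominal"

    def __post_init__(self) -> None:
        if self.sense not in (">=", "<"):
            raise ValueError(f"unknown goal sense {self.sense!r}")
        if self.scope not in ("nominal", "worst"):
            raise ValueError(f"unknown goal scope {self.scope!r}")


def default_clinical_goals() -> list[ClinicalGoal]:
    """The lung planning goal set used throughout this package.

    Nominal goals: CTV D98% >= 57 Gy and D1% < 63 Gy; esophagus and heart
    D0.04cc < 60 Gy; heart and healthy-lung mean < 20 Gy; lung V30Gy < 20%;
    spinal canal D0.04cc < 50 Gy; body D1cc < 63 Gy.  Worst-case goals:
    CTV D95% >= 57 Gy, spinal canal D0.04cc < 50 Gy, body D1cc < 63 Gy.
    """
    return [
        ClinicalGoal("CTV", "D98%", ">=", 57.0, "nominal"),
        ClinicalGoal("CTV", "D1%", "<", 63.0, "nominal"),
        ClinicalGoal("Esophagus", "D0.04cc", "<", 60.0, "nominal"),
        ClinicalGoal("Heart", "Dmean", "<", 20.0, "nominal"),
        ClinicalGoal("Heart", "D0.04cc", "<", 60.0, "nominal"),
        ClinicalGoal("Lungs-GTV", "Dmean", "<", 20.0, "nominal"),
        ClinicalGoal("Lungs-GTV", "V30Gy", "<", 20.0, "nominal"),
        ClinicalGoal("SpinalCanal", "D0.04cc", "<", 50.0, "nominal"),
        ClinicalGoal("Body", "D1cc", "<", 63.0, "nominal"),
        ClinicalGoal("CTV", "D95%", ">=", 57.0, "worst"),
        ClinicalGoal("SpinalCanal", "D0.04cc", "<", 50.0, "worst"),
        ClinicalGoal("Body", "D1cc", "<", 63.0, "worst"),
    ]


def load_clinical_goals(path: str) -> list[ClinicalGoal]:
    with open(path) as fh:
        rows = yaml.safe_load(fh)
    return [ClinicalGoal(**r) for r in rows]


def save_clinical_goals(goals: list[ClinicalGoal], path: str) -> None:
    rows = [
        {"roi": g.roi, "metric": g.metric, "sense": g.sense, "limit": g.limit, "scope": g.scope}
        for g in goals
    ]
    with open(path, "w") as fh:
        yaml.safe_dump(rows, fh)


def worst_case_metrics(
    table: dict[tuple[int, str], DVHCurve],
    goals: list[ClinicalGoal],
    scenarios: list[ScenarioSpec],
) -> pd.DataFrame:
    """Per-goal report: nominal value, worst value over scenarios, pass/fail.

    For '>=' goals the worst value is the minimum over scenarios; for '<'
    goals the maximum.  Goals with scope 'nominal' are judged on the
    nominal scenario only.
    """
    if not table:
        raise ValueError("empty scenario table")
    nom_idx = next((i for i, s in enumerate(scenarios) if s.is_nominal), 0)
    rows = []
    for g in goals:
        vals = []
        for i in range(len(scenarios)):
            key = (i, g.roi)
            if key not in table:
                raise ValueError(f"no DVH for ROI {g.roi!r} in scenario {i}")
            vals.append(table[key].metric(g.metric))
        vals = np.asarray(vals)
        nominal = vals[nom_idx]
        worst = float(vals.min() if g.sense == ">=" else vals.max())
        judged = nominal if g.scope == "nominal" else worst
        ok = judged >= g.limit if g.sense == ">=" else judged < g.limit
        rows.append(
            {
                "roi": g.roi,
                "metric": g.metric,
                "goal": f"{g.sense} {g.limit:g}",
                "scope": g.scope,
                "nominal": float(nominal),
                "worst": worst,
                "pass": bool(ok),
            }
        )
    return pd.DataFrame(rows)
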