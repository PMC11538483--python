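"""Worst-case robustness evaluation of an optimized plan.

Evaluates the plan under the 84-scenario evaluation grid on the *raw* CTV
and prints the clinical-goal report: nominal value, worst value over all
scenarios, and pass/fail per goal.
"""

import warnings

import arcplan as ap

warnings.filterwarnings("ignore", message=".*converge.*")

cfg = ap.PhantomConfig(shape=(48, 48, 48), spacing=(3.5, 3.5, 3.5))
setup = ap.default_setup(cfg)
plan = ap.make_plan(setup, "IMPT", lateral_spacing_mm=6.0)
plan = ap.optimize_and_normalize(setup, plan, max_iter=150)

# evaluation re-uses the optimization grid magnitude here; a non-isotropic
# evaluation margin can be supplied via per_direction_mm
scenarios = ap.enumerate_scenarios(setup.optimizer_setup_mm, setup.range_error,
                                   list(range(len(setup.phase_densities))))
print(f"evaluating {len(scenarios)} scenarios on the raw CTV and OARs ...")
table = ap.evaluate_scenarios(
    plan, scenarios, setup.phase_densities, setup.structures,
    eval_rois=["CTV", "Esophagus", "Heart", "Lungs-GTV", "SpinalCanal", "Body"],
)
report = ap.worst_case_metrics(table, ap.default_clinical_goals(), scenarios)
print(report.to_string(index=False, float_format=lambda v: f"{v:.2f}"))
# 'worst' is per metric: min over scenarios for coverage goals, max for
# sparing goals; each metric's worst value may come from a different scenario.
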