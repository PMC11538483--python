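"""Interplay (4D dynamic dose) simulation with DVH-band statistics.

Runs the full 4DDD loop for every starting phase of the breathing cycle:
spot delivery times, spot-to-phase distribution, per-phase partial doses,
exact-DVF warp to MidP, accumulation — then summarizes CTV D98% and D1%
bands over the 10 scenarios, plus the beam delivery time.
"""

import warnings

import numpy as np

import arcplan as ap

warnings.filterwarnings("ignore", message=".*converge.*")

cfg = ap.PhantomConfig(shape=(48, 48, 48), spacing=(3.5, 3.5, 3.5))
setup = ap.default_setup(cfg)
plan = ap.make_plan(setup, "IMPT", lateral_spacing_mm=6.0)
plan = ap.optimize_and_normalize(setup, plan, max_iter=150)

sched = ap.simulate_timing(plan)
print(f"IMPT BDT = {sched.total_bdt_s:.1f} s "
      f"(inter-beam travel {sched.inter_beam_travel_s:.1f} s)")

band, scenarios = ap.interplay_bands(plan, setup.phases, setup.structures)
print(f"interplay scenarios (starting phases): {len(scenarios)}")
for m in ("D98%", "D1%"):
    vals = band.per_scenario[m]
    print(f"CTV {m}: per-scenario {np.round(vals, 2)} Gy")
    print(f"        band = [{band.minimum[m]:.2f}, {band.maximum[m]:.2f}] Gy, "
          f"width = {band.bandwidth[m]:.2f} Gy")
# A narrower band means the delivered dose depends less on where in the
# breathing cycle delivery starts, i.e. the plan is more interplay-robust.
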