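# arcplan

Desk-scale comparison of proton arc therapy (PAT) and intensity-modulated
proton therapy (IMPT) for moving lung tumors: synthetic 4D thorax
phantoms, simplified pencil-beam planning with worst-case minimax robust
optimization, scenario-based robustness evaluation, NTCP and
beam-delivery-time models, and 4D dynamic dose (interplay) simulation with
DVH-band statistics.

The package is for medical-physics researchers who want to study the
*methodology* of PAT-vs-IMPT plan comparison — scenario grids, robust
optimization behavior, interplay bands, paired statistics — on fully
synthetic, ground-truth-known data, without a commercial treatment
planning system. It is an analysis pipeline, not a clinical dose engine:
the dose model is an analytic Bragg-curve / water-equivalent-path-length
surrogate that responds physically to setup shifts, range errors and
breathing-phase density changes, but makes no Monte Carlo accuracy claims.

## What it computes

- **Phantom**: a P-phase (default 10) breathing series in which a
  spherical GTV translates along a 1-cos cranio-caudal path inside a
  low-density lung, with analytically known deformation vector fields to
  the time-weighted mid-position (MidP) reference, plus Body / Lungs /
  Heart / Esophagus / SpinalCanal / GTV / CTV masks (CTV = GTV + 5 mm).
- **Plans**: 3-beam IMPT, or a one-revolution arc at 1–2° gantry spacing
  with exactly one energy layer per direction chosen by a geometric
  mid-depth heuristic (an ELSA-style contract).
- **Robust optimization**: spot weights w ≥ 0 minimizing
  `max_s f_s(w) + g(w)` over the scenario grid
  (setup ±5 mm in 6 directions + nominal) × (range ±3% + nominal) ×
  (4 phases) = 84 scenarios, where `f_s` are quadratic penalties on the
  expanded target under scenario `s` and `g` holds the nominal OAR terms.
  All plans are normalized to CTV D50% = 60 Gy (30 × 2 Gy).
- **Evaluation**: DVH metrics (Dx%, Dycc, VxGy, Dmean), homogeneity index
  (D2%−D98%)/D50%, Paddick conformity index, body integral dose, clinical
  goal tables with per-metric worst case over scenarios, logistic NTCP
  models driven by mean heart / lung / esophageal dose, and beam delivery
  time (start-and-stop for IMPT with inter-beam travel; continuous
  rotation with zero inter-beam travel for the arc).
- **Interplay**: 4D dynamic dose — spot delivery times, spot-to-phase
  distribution over the breathing period, per-phase partial doses warped
  to MidP and accumulated; one scenario per starting phase (10 total),
  summarized by CTV D98%/D1% bandwidths (max − min).
- **Statistics**: paired Wilcoxon signed-rank comparison (exact
  distribution for n ≤ 25) of any per-patient metric table.

## Worked example

```python
import arcplan as ap

setup = ap.default_setup()                       # 64^3 phantom + 84 scenarios
plan  = ap.make_plan(setup, "IMPT", lateral_spacing_mm=6.0)
plan  = ap.optimize_and_normalize(setup, plan, max_iter=80)
dose  = ap.compute_dose(plan, setup.phases.midp)
ctv   = ap.DVHCurve.from_dose(dose, setup.structures["CTV"])
print(ctv.d_percent(98), ctv.d_percent(50), ctv.d_percent(1))
```

Running `python examples/02_plan_and_optimize.py` (the same chain with
reporting) prints, on the default phantom:

```
optimization scenarios: 84
IMPT: beams [45.0, 170.0, 350.0], 23 energy layers, 278 spots
CTV  D98% = 52.16 Gy   (goal >= 57 Gy)
CTV  D50% = 60.000 Gy  (normalized to 60 Gy)
CTV  D1%  = 69.00 Gy   (goal < 63 Gy)
HI = 0.247 (0 = homogeneous), CI = 0.175 (Paddick, 1 = conformal), body ID = 9408 Gy.cc
Heart      mean dose = 0.29 Gy
Lungs-GTV  mean dose = 5.80 Gy
Esophagus  mean dose = 0.18 Gy
```

D50% is exactly the prescription because normalization is a single global
rescale of the (linear) dose; D98%/D1% show the coverage/hot-spot spread
this coarse engine achieves under worst-case robust optimization — wider
than a clinical TPS would deliver, which is expected at this resolution.
The remaining examples cover phantom construction (`01`), the 84-scenario
worst-case goal report (`03`), interplay DVH bands and delivery time
(`04`), and a paired IMPT-vs-PAT phantom-cohort comparison with Wilcoxon
statistics (`05`).

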