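# Methods

This note documents the models behind `arcplan`, the assumptions they
make, the parameters that matter, and what the synthetic pipeline can and
cannot say about real patient data.

## Synthetic 4D phantom

The phantom is a 160 mm cube (64³ voxels at 2.5 mm by default; tests use
coarser grids) containing piecewise-constant relative-density surrogates:
body 1.0, lung 0.26, tumor 1.05, vertebral bone 1.4, air 0.001. Only
relative stopping power matters to the dose engine, so no CT-number
calibration is attempted. Organs are analytic solids (elliptic-cylinder
body and lungs, ellipsoidal heart, tubular esophagus and spinal canal);
the GTV is a sphere (10 mm radius by default) in the right lung whose
partial-volume edge spans one voxel.

**Motion.** The tumor translates cranio-caudally along a 1-cos trajectory
`z_p = A (1 − cos 2πp/P)/2` (peak-to-peak amplitude A = 8 mm, P = 10
phases, 4 s period by default; amplitude and period are not dictated by
any dataset and were chosen as typical mid-lobe lung-tumor values). The
deformation field of each phase toward the time-weighted mid-position
(MidP) equals the full tumor displacement inside an inner sphere covering
the tumor path, decays smoothly (C¹ cosine ramp over 12 mm) to zero well
inside the lung, and is zero elsewhere. Because the displacement is
spatially constant wherever density differs from the lung background, the
field is exactly invertible there.

**Grid snapping.** By default per-phase offsets — and the MidP position
itself — are snapped to whole voxels (`snap_motion_to_grid`). Every
phase-to-MidP warp is then an integer translation, so MidP reconstruction
and 4D dose accumulation are exact to machine precision rather than
accurate to interpolation error; the snapped MidP sits within half a
voxel of the true time-weighted mean position. Disabling snapping gives
continuous trajectories with trilinear-interpolation warps.

Phase weights are uniform 1/P (no per-phase dwell information exists for
a regular coached breathing pattern). Randomness enters only through
optional density noise; geometry is deterministic.

## Dose engine

A pencil-beam surrogate: each spot is a parallel ray through the
isocenter plane at gantry angle θ (axial rotation; θ = 0 enters
anteriorly). The cumulative water-equivalent path length (WEPL) along the
central ray is integrated at 1 mm steps on trilinearly sampled density;
voxel dose is

`D(v) = w · B(WEPL(depth_v); R·s) · exp(−r_v²/2σ²) / 2πσ²`,

with `B` the Bortfeld analytic Bragg curve (power-law plateau plus a
range-straggled peak via parabolic cylinder functions; straggling width
0.012·R^0.935 cm), `R` the nominal range of the energy layer, `s` the
scenario's range-scale, and `σ(z) = σ₀ + kz` the depth-linear lateral
width (σ₀ = 5 mm, k = 0.025). The range parameter coincides with the
distal ~80% falloff to within a millimeter. Setup errors shift every ray
by the negative of the patient shift; range errors rescale `R`; phase
scenarios swap the density volume. Dose is exactly linear in spot
weights, which the optimizer exploits through per-scenario influence
matrices. No nuclear halo, RBE weighting, or heterogeneity-induced
lateral asymmetry is modeled; a range shifter is a constant WEPL offset,
off by default. The machine description (energy ladder 40–300 mm WEPL in
2.5 mm steps, spot width, timing constants) is a generic
pencil-beam-scanning surrogate, YAML-overridable — no real machine's
parameters are public at this level.

## Plans

**IMPT** (3 beams, default angles 350°/45°/170°, set so every beam's
distal edge exits laterally rather than into the mediastinum of this
right-sided phantom): per beam, a rectangular lateral grid (6–10 mm
spacing) covers the target projection, and per lateral cell the energy
ladder covers the cell's WEPL interval padded by 3 mm.

**PAT (ELSA-style)**: one revolution at 1–2° spacing (overridable for
deliberately coarse experiments), exactly one energy layer per direction.
The published contract of the commercial algorithm is honored — one
geometry-driven layer per direction, chosen from a predetermined ladder —
without claiming to replicate its proprietary selection: our heuristic
puts the Bragg peak at the target's mid WEPL depth along each direction's
central axis, then bounds the energy-index step between adjacent
directions (≤ 2 ladder steps) as a deliverability surrogate. Directions
whose proximal corridor (15 mm radius) crosses a configured avoidance ROI
carry no spots.

## Minimax robust optimization

Objectives are quadratic one-sided penalties (min/max/mean dose),
normalized per voxel and per dose level. Robust terms concern only the
expanded target CTVexp — the CTV grown by the geometric remainder after
the total setup margin (8 mm isotropic by default; Van Herk-style
recipes with configurable coefficients can generate anisotropic totals)
is split into a 5 mm optimizer setup-error magnitude plus expansion.
The worst case over scenarios is smoothed by log-sum-exp with a
decreasing temperature ladder (1e-2, 1e-3 in objective units) and
minimized by L-BFGS-B under w ≥ 0; ties between equally worst scenarios
resolve by fixed enumeration order. ROIs larger than the point budget
(3000–4000 points) are subsampled with a bias toward the target, where
max-dose violations actually occur. Reported diagnostics always use the
exact (unsmoothed) max. The smoothing bias is ~1e-3 relative at the
optimum on toy problems with exhaustive-search solutions.

Scenario grids are the product construction: six axis-aligned shifts of
the setup magnitude plus the nominal position, range scales
{1−ρ, 1, 1+ρ}, and the chosen phases (MidP, end-exhale, end-inhale,
mid-ventilation by default), giving 7 × 3 × 4 = 84. Evaluation uses the
raw CTV, optionally with anisotropic per-direction shift magnitudes; the
worst case is per metric (each metric's extreme may come from a different
scenario), min over scenarios for coverage goals and max for sparing
goals.

## Interplay (4D dynamic dose)

Delivery timing: spots are sequential within a layer (dwell =
weight/rate, 2 ms lateral switch), layers within a beam switch energy
downward (0.6 s) or upward (5 s); IMPT inserts inter-beam travel (gantry
rotation at 6°/s plus a 20 s fixed overhead); the arc rotates
continuously, never faster than the gantry speed limit and never arriving
before its energy switch completes, with inter-beam travel identically
zero. Spots are instantaneous at their start time. A spot delivered at
time t belongs to phase `floor(((t mod T)/T)·P + start) mod P` (uniform
dwell). Partial doses are computed per phase on that phase's density,
pulled back to MidP with the phase's exact field (trilinear pull-back;
an optional mass-weighted, energy-conserving variant exists because the
registration scheme such accumulations use clinically is not uniquely
defined), and summed. Accumulation iterates in a canonical bin order so
scenarios with identical addends sum bitwise identically — a
zero-amplitude phantom therefore yields exactly zero bandwidth. One
fraction is simulated; multi-fraction averaging is deliberately out of
scope. DVH bands report min/max/width of CTV D98% and D1% over the 10
starting-phase scenarios.

## NTCP and statistics

NTCP models are logistic, `p = 1/(1+exp(−S))`, with
`S = b₀ + b₁·(mean organ dose) + Σ covariates`: 2-year mortality from
mean heart dose, grade ≥ 2 pneumonitis from mean lung dose, grade ≥ 2
dysphagia from mean esophageal dose. The shipped coefficients are
representative of published fits for these endpoints (per-Gy slopes
0.06–0.13) and are explicitly *editable model parameters*: any clinical
interpretation requires substituting the coefficients of the protocol in
force. Only nominal-scenario doses drive NTCP.

Cohort comparisons use the two-sided Wilcoxon signed-rank test (exact
distribution for n ≤ 25, normal approximation above; zeros dropped),
reporting the median of paired differences. No multiple-testing
correction is applied; p-values are per metric.

## Numerical conventions and limitations

- Margins are Minkowski dilations on voxel centers (exact Euclidean
  distance transform); chained digital dilations are *contained in* the
  one-shot dilation of the summed margin — digitization loses sub-voxel
  reach — the reverse of the continuous identity.
- Dx% uses linear interpolation between sorted voxel doses (`quantile`);
  absolute-volume metrics reuse the same interpolation on the cumulative
  volume axis.
- The logistic NTCP saturates to exactly 1.0 in double precision for
  linear predictors beyond ~40.
- Problem sizes: the shipped examples and the acceptance script run the
  full 84-scenario optimization at 64³/2.5 mm (≈ 280 spots, under a
  minute); the test suite uses 32³–48³ phantoms and reduced scenario
  sets, chosen so the whole suite exercises every contract in seconds.
- What passing tests show — and don't: the phantom has rigid, periodic,
  grid-aligned motion, piecewise-constant densities and exactly known
  deformation fields. Results transfer to the *mechanics* of scenario
  enumeration, robust optimization, accumulation and statistics, not to
  clinical dose accuracy, real breathing irregularity, baseline drift, or
  deformable anatomy. Cohort-level findings (which modality is more
  robust, NTCP deltas, delivery-time gaps) depend on the phantom
  population and the surrogate machine model and should be read as
  demonstrations of the analysis, not clinical conclusions.
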