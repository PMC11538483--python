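"""Build a synthetic 4D breathing thorax phantom and inspect its motion.

Creates the default 10-phase series (64^3 voxels at 2.5 mm) with an 8 mm
peak-to-peak cranio-caudal tumor trajectory, reconstructs the
time-weighted mid-position (MidP) image from the phases and their exact
deformation fields, and prints the ground-truth tumor path.
"""

import numpy as np

import arcplan as ap

p4d, structures = ap.build_phantom(ap.PhantomConfig())

print(f"phases: {p4d.n_phases}, period: {p4d.period_s} s")
print("per-phase GTV center z (mm):",
      np.round(p4d.gtv_centers_mm[:, 2], 2))
print(f"MidP GTV center z: {p4d.midp_center_mm[2]:.2f} mm "
      "(time-weighted mean of the trajectory, snapped to the grid)")

rec = ap.reconstruct_midp(p4d)
err = np.abs(rec.values - p4d.midp.values).max()
print(f"MidP reconstruction max |error|: {err:.2e} relative density")
print("ROIs:", ", ".join(structures.names()))
gtv_cc = structures["GTV"].values.sum() * structures["GTV"].voxel_volume_cc
ctv_cc = structures["CTV"].values.sum() * structures["CTV"].voxel_volume_cc
print(f"GTV volume: {gtv_cc:.1f} cc; CTV (GTV + 5 mm): {ctv_cc:.1f} cc")
# The error being ~0 confirms the deformation fields exactly invert the
# applied motion, which is what makes downstream dose accumulation exact.
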