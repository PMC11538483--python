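"""Simplified pencil-beam spot dose engine on voxel grids.

Each spot is a ray through the isocenter plane, traced through the density
volume to obtain the cumulative water-equivalent path length (WEPL); dose
at a voxel is weight x Bragg(depth-dose at the voxel's WEPL depth) x a
lateral Gaussian whose sigma grows with depth.  Setup errors rigidly shift
the patient (realized as the opposite shift of every beam ray); range
errors scale the nominal range of the depth-dose curve.  The engine is
linear in spot weights by construction, which the planner exploits through
per-scenario dose-influence matrices.

Geometry conventions: world coordinates in mm, axes (x, y, z) with z the
cranio-caudal axis.  Gantry angle theta rotates in the axial (x, y) plane;
theta = 0 deg enters from the anterior (-y) side traveling toward +y.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bragg import MachineModel, bragg_depth_dose
from .volumes import VoxelVolume

__all__ = [
    "Spot",
    "EnergyLayer",
    "DoseDistribution",
    "beam_axes",
    "ray_wepl",
    "spot_dose",
    "compute_dose",
    "influence_matrix",
]


@dataclass
class Spot:
    """One scanned pencil-beam spot."""

    angle_deg: float
    u_mm: float  # lateral beam's-eye-view coordinate in the axial plane
    v_mm: float  # lateral beam's-eye-view coordinate along z
    range_mm: float  # nominal range, mm water-equivalent
    weight: float = 0.0  # MU-like, >= 0

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ValueError("spot weight must be >= 0")


@dataclass
class EnergyLayer:
    """Spots sharing one gantry angle and one energy (nominal range)."""

    angle_deg: float
    range_mm: float
    spots: list[Spot] = field(default_factory=list)

    def __post_init__(self) -> None:
        for s in self.spots:
            if abs(s.angle_deg - self.angle_deg) > 1e-9 or abs(s.range_mm - self.range_mm) > 1e-9:
                raise ValueError("all spots in a layer must share its angle and energy")


@dataclass
class DoseDistribution:
    """Dose volume (Gy) plus provenance."""

    volume: VoxelVolume
    provenance: str = ""

    def __post_init__(self) -> None:
        v = self.volume.values
        if not np.all(np.isfinite(v)) or (v < -1e-12).any():
            raise ValueError("dose must be finite and >= 0")

    @property
    def values(self) -> np.ndarray:
        return self.volume.values


def beam_axes(angle_deg: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unit beam direction b and lateral axes (e_u in-plane, e_v = z)."""
    th = np.deg2rad(angle_deg)
    b = np.array([np.sin(th), np.cos(th), 0.0])
    e_u = np.array([np.cos(th), -np.sin(th), 0.0])
    e_v = np.array([0.0, 0.0, 1.0])
    return b, e_u, e_v


def _grid_ray_interval(vol: VoxelVolume, p: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Parametric [t0, t1] of the ray p + t b inside the grid bounding box."""
    lo = np.asarray(vol.origin) - np.asarray(vol.spacing) / 2.0
    hi = lo + np.asarray(vol.shape) * np.asarray(vol.spacing)
    t0, t1 = -np.inf, np.inf
    for i in range(3):
        if abs(b[i]) < 1e-12:
            if not (lo[i] <= p[i] <= hi[i]):
                return 0.0, -1.0  # misses the grid
        else:
            ta = (lo[i] - p[i]) / b[i]
            tb = (hi[i] - p[i]) / b[i]
            t0 = max(t0, min(ta, tb))
            t1 = min(t1, max(ta, tb))
    return t0, t1


def ray_wepl(
    density: VoxelVolume, point: np.ndarray, direction: np.ndarray, step_mm: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative WEPL along the ray through ``point`` with unit ``direction``.

    Returns (t_samples, wepl_samples): geometric distance from grid entry
    and the accumulated density-weighted path length (midpoint rule on
    trilinearly sampled density).  A ray missing the grid returns empty
    arrays.
    """
    b = np.asarray(direction, dtype=float)
    b = b / np.linalg.norm(b)
    t0, t1 = _grid_ray_interval(density, np.asarray(point, dtype=float), b)
    if t1 <= t0:
        return np.empty(0), np.empty(0)
    n = max(int(np.ceil((t1 - t0) / step_mm)), 1)
    edges = np.linspace(t0, t1, n + 1)
    mids = 0.5 * (edges[:-1] + edges[1:])
    pts = np.asarray(point)[None, :] + mids[:, None] * b[None, :]
    # nearest-edge extension: the bbox reaches half a voxel beyond the
    # outermost centers, where constant-zero padding would under-integrate
    rho = density.sample(pts, mode="nearest")
    seg = np.diff(edges)
    wepl = np.concatenate([[0.0], np.cumsum(rho * seg)])
    return edges, wepl


def spot_dose(
    spot: Spot,
    density: VoxelVolume,
    setup_shift_mm: np.ndarray = (0.0, 0.0, 0.0),
    range_scale: float = 1.0,
    *,
    iso_mm: np.ndarray | None = None,
    machine: MachineModel | None = None,
    points: np.ndarray | None = None,
    unit_weight: bool = False,
) -> np.ndarray | DoseDistribution:
    """Dose of a single spot under a rigid setup shift and range scaling.

    Parameters
    ----------
    points : (N, 3) array, optional
        Evaluate at these world points and return a 1-D array (used for
        influence matrices); otherwise a full-grid DoseDistribution.
    unit_weight : bool
        Ignore ``spot.weight`` and deposit with weight 1 (influence rows).
    """
    if range_scale <= 0:
        raise ValueError("range_scale must be > 0")
    machine = machine or MachineModel()
    iso = np.asarray(iso_mm if iso_mm is not None else _grid_center(density), dtype=float)
    shift = np.asarray(setup_shift_mm, dtype=float)

    b, e_u, e_v = beam_axes(spot.angle_deg)
    # a rigid patient shift +s == shifting every beam ray by -s
    q = iso + spot.u_mm * e_u + spot.v_mm * e_v - shift

    t, wepl = ray_wepl(density, q, b, machine.ray_step_mm)
    w = 1.0 if unit_weight else spot.weight
    if t.size == 0 or w == 0.0:
        if points is not None:
            return np.zeros(len(points))
        return DoseDistribution(density.zeros_like(), provenance="miss")

    r_eff = spot.range_mm * range_scale
    wepl_off = machine.range_shifter_wepl_mm

    if points is None:
        pts = np.stack(density.grid_coords(), axis=-1).reshape(-1, 3)
    else:
        pts = np.asarray(points, dtype=float)
    rel = pts - q
    depth = rel @ b
    lat2 = np.einsum("ij,ij->i", rel, rel) - depth**2

    sig_max = machine.sigma_at(r_eff)
    cut2 = (machine.lateral_cutoff_sigma * sig_max) ** 2
    live = (lat2 <= cut2) & (depth >= t[0]) & (depth <= t[-1])
    dose_flat = np.zeros(len(pts))
    if live.any():
        z_eff = np.interp(depth[live], t, wepl) + wepl_off
        dd = bragg_depth_dose(z_eff, r_eff)
        sig = machine.sigma_at(np.minimum(z_eff, r_eff))
        gauss = np.exp(-0.5 * lat2[live] / sig**2) / (2.0 * np.pi * sig**2)
        # the 100 mm^2 factor keeps typical voxel doses O(1) per unit weight
        dose_flat[live] = w * dd * gauss * 100.0
    if points is not None:
        return dose_flat
    return DoseDistribution(
        density.like(dose_flat.reshape(density.shape)),
        provenance=f"spot@{spot.angle_deg:.1f}deg",
    )


def _grid_center(vol: VoxelVolume) -> np.ndarray:
    return np.asarray(vol.origin) + (np.asarray(vol.shape) - 1) * np.asarray(vol.spacing) / 2.0


def iter_spots(plan) -> list[Spot]:
    """Flatten a plan's layers into its spot list (fixed order)."""
    return [s for layer in plan.layers for s in layer.spots]


def compute_dose(
    plan,
    density: VoxelVolume,
    setup_shift_mm: np.ndarray = (0.0, 0.0, 0.0),
    range_scale: float = 1.0,
    *,
    machine: MachineModel | None = None,
    iso_mm: np.ndarray | None = None,
    provenance: str = "",
    spots: list[Spot] | None = None,
) -> DoseDistribution:
    """Superpose all (or a subset of) plan spots on one density volume."""
    machine = machine or getattr(plan, "machine", None) or MachineModel()
    iso = iso_mm if iso_mm is not None else getattr(plan, "iso_mm", None)
    acc = np.zeros(density.shape)
    for s in spots if spots is not None else iter_spots(plan):
        if s.weight == 0.0:
            continue
        d = spot_dose(
            s, density, setup_shift_mm, range_scale, iso_mm=iso, machine=machine
        )
        acc += d.values
    return DoseDistribution(density.like(acc), provenance=provenance)


def influence_matrix(
    spots: list[Spot],
    density: VoxelVolume,
    points: np.ndarray,
    setup_shift_mm: np.ndarray = (0.0, 0.0, 0.0),
    range_scale: float = 1.0,
    *,
    machine: MachineModel | None = None,
    iso_mm: np.ndarray | None = None,
) -> np.ndarray:
    """Per-unit-weight dose of every spot at every point: (N_points, N_spots).

    Dose of the plan at the points is then simply ``A @ weights``.
    """
    machine = machine or MachineModel()
    A = np.zeros((len(points), len(spots)), dtype=np.float32)
    for j, s in enumerate(spots):
        A[:, j] = spot_dose(
            s,
            density,
            setup_shift_mm,
            range_scale,
            iso_mm=iso_mm,
            machine=machine,
            points=points,
            unit_weight=True,
        )
    return A
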