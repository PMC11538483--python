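"""Synthetic 4D breathing thorax phantoms with known ground-truth motion.

Generates a 10-phase (configurable) breathing series of density volumes in
which a spherical gross tumor volume (GTV) translates cranio-caudally along
a 1-cos trajectory inside a low-density lung, together with the exact
deformation vector field (DVF) mapping each phase onto the time-weighted
mid-position (MidP) reference, and the ROI masks the planning and
evaluation stages need (Body, Lungs, Heart, Esophagus, SpinalCanal, GTV,
CTV, Lungs-GTV).

The motion model is a rigid translation of the tumor inside a smooth
"motion envelope": the DVF equals the full tumor displacement within an
inner sphere around the tumor path and decays smoothly to zero before
reaching the lung boundary.  Because the displacement is spatially constant
wherever the density actually differs from the lung background, the DVFs
are exactly invertible there, which is what makes exact dose-accumulation
oracles possible downstream.  By default per-phase tumor offsets are
snapped to the voxel grid so that warping phases back to MidP is exact
(integer shifts) rather than merely accurate to interpolation error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .volumes import VoxelVolume

__all__ = [
    "PhantomConfig",
    "Phase4DSet",
    "StructureSet",
    "build_phantom",
    "reconstruct_midp",
    "cos_trajectory_offsets",
]


@dataclass
class PhantomConfig:
    """Parameters of the synthetic thorax.

    Geometry is parameterized in mm relative to the grid center; defaults
    suit the default 64**3 grid at 2.5 mm spacing (160 mm cube).  Densities
    are relative stopping-power surrogates, not calibrated CT numbers.
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (2.5, 2.5, 2.5)
    n_phases: int = 10
    period_s: float = 4.0
    #: peak-to-peak cranio-caudal tumor motion amplitude, mm
    amplitude_mm: float = 8.0
    gtv_radius_mm: float = 10.0
    #: GTV center at mid-exhale (trajectory minimum), mm relative to grid center
    gtv_center_mm: tuple[float, float, float] = (38.0, -5.0, -2.0)
    #: snap per-phase tumor offsets to whole voxels (exact DVF warps)
    snap_motion_to_grid: bool = True
    phase_weights: tuple[float, ...] | None = None  # None -> uniform 1/P
    #: optional zero-mean Gaussian density noise (std, relative density units)
    noise_sigma: float = 0.0
    seed: int = 0

    # piecewise-constant density surrogates
    density_body: float = 1.0
    density_lung: float = 0.26
    density_tumor: float = 1.05
    density_bone: float = 1.4

    # organ geometry (mm, relative to grid center unless noted)
    lung_center_x_mm: float = 38.0
    lung_semiaxes_mm: tuple[float, float] = (26.0, 42.0)  # (x, y) of each lung
    heart_center_mm: tuple[float, float, float] = (-10.0, 8.0, -8.0)
    heart_semiaxes_mm: tuple[float, float, float] = (22.0, 20.0, 26.0)
    esophagus_center_xy_mm: tuple[float, float] = (0.0, 18.0)
    esophagus_radius_mm: float = 5.0
    canal_center_xy_mm: tuple[float, float] = (0.0, 48.0)
    canal_radius_mm: float = 6.0
    vertebra_radius_mm: float = 12.0
    body_semiaxes_mm: tuple[float, float] = (72.0, 62.0)


@dataclass
class StructureSet:
    """Named boolean ROI masks on the MidP grid."""

    rois: dict[str, VoxelVolume]

    def __getitem__(self, name: str) -> VoxelVolume:
        if name not in self.rois:
            raise KeyError(f"unknown ROI {name!r}; have {sorted(self.rois)}")
        return self.rois[name]

    def __contains__(self, name: str) -> bool:
        return name in self.rois

    def names(self) -> list[str]:
        return sorted(self.rois)

    def mask(self, name: str) -> np.ndarray:
        return self[name].values

    def add(self, name: str, mask: VoxelVolume) -> None:
        self.rois[name] = mask


@dataclass
class Phase4DSet:
    """Ordered breathing phases with exact per-phase DVFs to MidP.

    ``dvf_to_midp[p]`` has shape (3, nx, ny, nz) and holds, per voxel, the
    displacement u (mm) such that a point x in phase-p coordinates maps to
    x + u(x) in MidP coordinates.
    """

    phases: list[VoxelVolume]
    dvf_to_midp: list[np.ndarray]
    phase_weights: np.ndarray
    period_s: float
    midp: VoxelVolume
    #: ground-truth GTV center per phase and at MidP (world mm)
    gtv_centers_mm: np.ndarray = field(default=None)  # type: ignore[assignment]
    midp_center_mm: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if len(self.phases) < 1:
            raise ValueError("need at least one phase")
        self.phase_weights = np.asarray(self.phase_weights, dtype=float)
        if abs(self.phase_weights.sum() - 1.0) > 1e-9:
            raise ValueError("phase_weights must sum to 1")
        if len(self.dvf_to_midp) != len(self.phases):
            raise ValueError("one DVF per phase required")

    @property
    def n_phases(self) -> int:
        return len(self.phases)


def cos_trajectory_offsets(amplitude_mm: float, n_phases: int) -> np.ndarray:
    """Cranio-caudal 1-cos tumor offsets per phase, mm.

    Phase 0 is end-exhale (trajectory minimum); the tumor spends more time
    near exhale, as the 1-cos shape implies.  Offsets span [0, amplitude].
    """
    p = np.arange(n_phases)
    return amplitude_mm * (1.0 - np.cos(2.0 * np.pi * p / n_phases)) / 2.0


def _smooth_ball(X, Y, Z, center, radius, edge):
    """Partial-volume sphere indicator in [0, 1] with a linear edge."""
    d = np.sqrt((X - center[0]) ** 2 + (Y - center[1]) ** 2 + (Z - center[2]) ** 2)
    return np.clip((radius - d) / edge + 0.5, 0.0, 1.0)


def _paint_density(cfg: PhantomConfig, grid: VoxelVolume, tumor_center: np.ndarray) -> np.ndarray:
    """Analytic density painter; the tumor may sit at any (sub-voxel) center."""
    X, Y, Z = grid.grid_coords()
    c = _grid_center(cfg)
    x, y, z = X - c[0], Y - c[1], Z - c[2]

    dens = np.full(grid.shape, 0.001)  # air
    bx, by = cfg.body_semiaxes_mm
    body = (x / bx) ** 2 + (y / by) ** 2 <= 1.0
    dens[body] = cfg.density_body

    lungs = np.zeros(grid.shape, dtype=bool)
    lx, ly = cfg.lung_semiaxes_mm
    for sgn in (+1, -1):
        lungs |= ((x - sgn * cfg.lung_center_x_mm) / lx) ** 2 + (y / ly) ** 2 <= 1.0
    lungs &= body
    dens[lungs] = cfg.density_lung

    # vertebra with embedded spinal canal, both full-length tubes
    vx, vy = cfg.canal_center_xy_mm
    vert = (x - vx) ** 2 + (y - vy) ** 2 <= cfg.vertebra_radius_mm**2
    dens[vert & body] = cfg.density_bone

    # heart and esophagus are soft tissue; only their masks matter
    edge = min(cfg.spacing)
    tum = _smooth_ball(X, Y, Z, tumor_center, cfg.gtv_radius_mm, edge)
    dens = dens + tum * (cfg.density_tumor - dens)
    return dens


def _grid_center(cfg: PhantomConfig) -> np.ndarray:
    return (np.asarray(cfg.shape) - 1) * np.asarray(cfg.spacing) / 2.0


def _structure_masks(cfg: PhantomConfig, grid: VoxelVolume, midp_center: np.ndarray) -> StructureSet:
    from .structures import expand_isotropic

    X, Y, Z = grid.grid_coords()
    c = _grid_center(cfg)
    x, y, z = X - c[0], Y - c[1], Z - c[2]

    bx, by = cfg.body_semiaxes_mm
    body = (x / bx) ** 2 + (y / by) ** 2 <= 1.0
    lungs = np.zeros(grid.shape, dtype=bool)
    lx, ly = cfg.lung_semiaxes_mm
    for sgn in (+1, -1):
        lungs |= ((x - sgn * cfg.lung_center_x_mm) / lx) ** 2 + (y / ly) ** 2 <= 1.0
    lungs &= body
    hx, hy, hz = cfg.heart_semiaxes_mm
    hc = cfg.heart_center_mm
    heart = ((x - hc[0]) / hx) ** 2 + ((y - hc[1]) / hy) ** 2 + ((z - hc[2]) / hz) ** 2 <= 1.0
    ex, ey = cfg.esophagus_center_xy_mm
    eso = (x - ex) ** 2 + (y - ey) ** 2 <= cfg.esophagus_radius_mm**2
    vx, vy = cfg.canal_center_xy_mm
    canal = (x - vx) ** 2 + (y - vy) ** 2 <= cfg.canal_radius_mm**2

    gtv = (
        (X - midp_center[0]) ** 2 + (Y - midp_center[1]) ** 2 + (Z - midp_center[2]) ** 2
        <= cfg.gtv_radius_mm**2
    )
    rois = {
        "Body": grid.like(body),
        "Lungs": grid.like(lungs),
        "Heart": grid.like(heart & body),
        "Esophagus": grid.like(eso & body),
        "SpinalCanal": grid.like(canal & body),
        "GTV": grid.like(gtv),
    }
    ss = StructureSet(rois)
    ss.add("CTV", expand_isotropic(ss["GTV"], 5.0))
    ss.add("Lungs-GTV", grid.like(lungs & ~gtv))
    return ss


def build_phantom(cfg: PhantomConfig | None = None) -> tuple[Phase4DSet, StructureSet]:
    """Build the 4D phantom: P density phases, exact DVFs, MidP, and ROIs.

    Raises
    ------
    ValueError
        If the moving GTV would leave the grid or the lung at any phase.
    """
    cfg = cfg or PhantomConfig()
    if cfg.n_phases < 1:
        raise ValueError("n_phases must be >= 1")
    if cfg.amplitude_mm < 0:
        raise ValueError("amplitude_mm must be >= 0")

    grid = VoxelVolume(np.zeros(cfg.shape), cfg.spacing)
    c = _grid_center(cfg)
    base = c + np.asarray(cfg.gtv_center_mm)

    offsets = cos_trajectory_offsets(cfg.amplitude_mm, cfg.n_phases)
    if cfg.snap_motion_to_grid:
        offsets = np.round(offsets / cfg.spacing[2]) * cfg.spacing[2]
    if cfg.phase_weights is None:
        weights = np.full(cfg.n_phases, 1.0 / cfg.n_phases)
    else:
        weights = np.asarray(cfg.phase_weights, dtype=float)
        if len(weights) != cfg.n_phases:
            raise ValueError("phase_weights length must equal n_phases")
    mid_offset = float(np.sum(weights * offsets))
    if cfg.snap_motion_to_grid:
        # keep every phase-to-MidP displacement a whole number of voxels so
        # the pull-back warp is exact; moves MidP by at most half a voxel
        # from the true time-weighted mean position
        hz = cfg.spacing[2]
        mid_offset = float(np.round(mid_offset / hz) * hz)

    # feasibility: GTV inside grid and inside lung at every phase
    lx, ly = cfg.lung_semiaxes_mm
    extent_z = (np.asarray(cfg.shape)[2] - 1) * cfg.spacing[2]
    for o in offsets:
        center = base + np.array([0.0, 0.0, o])
        if not (cfg.gtv_radius_mm <= center[2] <= extent_z - cfg.gtv_radius_mm):
            raise ValueError(f"GTV leaves the grid at offset {o:+.1f} mm (z axis)")
        rel = np.asarray(cfg.gtv_center_mm)
        lat = np.hypot(
            (abs(rel[0]) - cfg.lung_center_x_mm) / lx, rel[1] / ly
        )
        if lat + cfg.gtv_radius_mm / min(lx, ly) > 1.0:
            raise ValueError("GTV exits the lung region")

    # motion-envelope window for the DVF: rigid inside r_in, cosine decay to r_out
    half_span = (offsets.max() - offsets.min()) / 2.0 if len(offsets) > 1 else 0.0
    r_in = cfg.gtv_radius_mm + half_span + 2.0 * min(cfg.spacing)
    r_out = r_in + 12.0
    mid_center = base + np.array([0.0, 0.0, mid_offset])

    X, Y, Z = grid.grid_coords()
    d_env = np.sqrt(
        (X - mid_center[0]) ** 2 + (Y - mid_center[1]) ** 2 + (Z - mid_center[2]) ** 2
    )
    window = np.clip((r_out - d_env) / (r_out - r_in), 0.0, 1.0)
    window = 0.5 - 0.5 * np.cos(np.pi * window)  # smooth C1 decay
    window = window.astype(np.float32)

    rng = np.random.default_rng(cfg.seed)
    phases: list[VoxelVolume] = []
    dvfs: list[np.ndarray] = []
    for o in offsets:
        dens = _paint_density(cfg, grid, base + np.array([0.0, 0.0, o]))
        if cfg.noise_sigma > 0:
            dens = np.clip(dens + rng.normal(0, cfg.noise_sigma, dens.shape), 0.0, None)
        phases.append(grid.like(dens))
        dz = mid_offset - o
        u = np.zeros((3,) + tuple(cfg.shape), dtype=np.float32)
        u[2] = dz * window
        dvfs.append(u)

    midp = grid.like(_paint_density(cfg, grid, mid_center))
    structures = _structure_masks(cfg, grid, mid_center)

    centers = np.stack([base + np.array([0.0, 0.0, o]) for o in offsets])
    p4d = Phase4DSet(
        phases=phases,
        dvf_to_midp=dvfs,
        phase_weights=weights,
        period_s=cfg.period_s,
        midp=midp,
        gtv_centers_mm=centers,
        midp_center_mm=mid_center,
    )
    return p4d, structures


def warp_to_midp(field: VoxelVolume, dvf: np.ndarray, order: int = 1) -> VoxelVolume:
    """Pull a phase-resolved field back onto the MidP grid.

    Uses the small-deformation inverse x = y - u(y), which is exact wherever
    the displacement is locally constant (the whole motion envelope interior
    for the rigid-translation phantom).
    """
    nx, ny, nz = field.shape
    I, J, K = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    sp = np.asarray(field.spacing)
    ci = I - dvf[0] / sp[0]
    cj = J - dvf[1] / sp[1]
    ck = K - dvf[2] / sp[2]
    from scipy.ndimage import map_coordinates

    vals = map_coordinates(
        field.values.astype(float), [ci, cj, ck], order=order, mode="constant", cval=0.0
    )
    return field.like(vals)


def reconstruct_midp(p4d: Phase4DSet) -> VoxelVolume:
    """Time-weighted MidP reconstruction: warp every phase to the reference
    configuration with its exact DVF and average with the phase weights."""
    if p4d.n_phases < 1:
        raise ValueError("empty phase list")
    acc = np.zeros(p4d.phases[0].shape)
    for w, phase, dvf in zip(p4d.phase_weights, p4d.phases, p4d.dvf_to_midp):
        acc += w * warp_to_midp(phase, dvf).values
    return p4d.phases[0].like(acc)


def mask_centroid(mask: VoxelVolume) -> np.ndarray:
    """World-coordinate centroid (mm) of a boolean or weighted mask."""
    vals = mask.values.astype(float)
    tot = vals.sum()
    if tot <= 0:
        raise ValueError("empty mask")
    idx = np.indices(mask.shape).reshape(3, -1)
    w = vals.reshape(-1)
    frac = (idx * w).sum(axis=1) / tot
    return mask.index_to_world(frac)


def density_centroid(
    vol: VoxelVolume, threshold: float, region: np.ndarray | None = None
) -> np.ndarray:
    """Centroid of the density excess above ``threshold``, optionally
    restricted to a region mask (tumor locator inside the lung)."""
    excess = np.clip(vol.values - threshold, 0.0, None)
    if region is not None:
        excess = excess * region
    return mask_centroid(vol.like(excess))
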