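"""Analytic Bragg-peak depth-dose curve and the machine beam model.

The pristine depth-dose uses Bortfeld's analytic parameterization of the
proton Bragg curve (power-law proximal plateau plus a range-straggled peak
expressed through parabolic cylinder functions).  It is a desk-scale
surrogate with a controllable range parameter, not a Monte Carlo engine:
nuclear halo, field-size effects and heterogeneity-induced lateral
asymmetries are outside its contract.

The range parameter R of the curve is the mean projected range in water
(mm), which for this parameterization coincides with the distal ~80%
falloff depth to well under a millimeter; the machine energy table is a
ladder of such nominal ranges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.special import pbdv

__all__ = ["bragg_depth_dose", "BraggCurve", "MachineModel"]

_P = 1.77  # exponent of the range-energy relation
_EPS = 0.1  # fraction of primary fluence in the low-energy tail


def _bortfeld_raw(z_cm: np.ndarray, r_cm: float) -> np.ndarray:
    """Unnormalized Bortfeld depth dose, z and R in cm."""
    sigma = 0.012 * r_cm**0.935  # range straggling width, cm
    z = np.asarray(z_cm, dtype=float)
    out = np.zeros_like(z)

    prox = z < r_cm - 10.0 * sigma
    if prox.any():
        rz = r_cm - z[prox]
        out[prox] = (
            17.93 * rz**-0.435 + (0.444 + 31.7 * _EPS / r_cm) * rz**0.565
        ) / (1.0 + 0.012 * r_cm)

    peak = (~prox) & (z <= r_cm + 5.0 * sigma)
    if peak.any():
        xi = (z[peak] - r_cm) / sigma
        d1 = pbdv(-0.565, -xi)[0]
        d2 = pbdv(-1.565, -xi)[0]
        out[peak] = (
            np.exp(-(xi**2) / 4.0)
            * sigma**0.565
            / (1.0 + 0.012 * r_cm)
            * (11.26 / sigma * d1 + (0.157 + 11.26 * _EPS / r_cm) * d2)
        )
    return out


class BraggCurve:
    """Depth-dose lookup for one nominal range, normalized to unit peak.

    Evaluation is by linear interpolation on a fine precomputed table,
    which keeps per-spot dose deposition cheap and vectorized.
    """

    def __init__(self, range_mm: float, step_mm: float = 0.25):
        if range_mm <= 0:
            raise ValueError("range must be positive")
        self.range_mm = float(range_mm)
        sigma_mm = 10.0 * 0.012 * (range_mm / 10.0) ** 0.935
        zmax = range_mm + 5.0 * sigma_mm
        self._z = np.arange(0.0, zmax + step_mm, step_mm)
        raw = _bortfeld_raw(self._z / 10.0, range_mm / 10.0)
        self._d = raw / raw.max()
        self.peak_depth_mm = float(self._z[np.argmax(self._d)])

    def __call__(self, z_mm: np.ndarray) -> np.ndarray:
        return np.interp(np.asarray(z_mm, dtype=float), self._z, self._d, left=0.0, right=0.0)


_CURVE_CACHE: dict[float, BraggCurve] = {}


def bragg_depth_dose(z_mm: np.ndarray, range_mm: float) -> np.ndarray:
    """Peak-normalized depth dose at water-equivalent depth z (mm)."""
    key = round(float(range_mm), 3)
    if key not in _CURVE_CACHE:
        _CURVE_CACHE[key] = BraggCurve(key)
    return _CURVE_CACHE[key](z_mm)


@dataclass
class MachineModel:
    """Surrogate pencil-beam-scanning machine description.

    The real study machine's physical parameters are not public; these
    defaults are generic PBS values and are meant to be overridden from a
    YAML file for any serious sensitivity study.
    """

    #: nominal ranges (mm water-equivalent) of the deliverable energies
    energy_ranges_mm: np.ndarray = field(
        default_factory=lambda: np.arange(40.0, 301.0, 2.5)
    )
    #: lateral spot sigma at zero depth, mm
    sigma0_mm: float = 5.0
    #: lateral sigma growth per mm of water-equivalent depth (unitless)
    sigma_growth: float = 0.025
    #: geometric step for ray WEPL integration, mm
    ray_step_mm: float = 1.0
    #: constant WEPL offset of an optional range shifter (0 = no shifter)
    range_shifter_wepl_mm: float = 0.0
    #: lateral dose cut-off in units of sigma
    lateral_cutoff_sigma: float = 3.5

    def __post_init__(self) -> None:
        self.energy_ranges_mm = np.sort(np.asarray(self.energy_ranges_mm, dtype=float))
        if len(self.energy_ranges_mm) == 0:
            raise ValueError("energy table must not be empty")

    def nearest_range(self, wepl_mm: float) -> float:
        """Deliverable nominal range closest to a requested WEPL depth."""
        i = int(np.argmin(np.abs(self.energy_ranges_mm - wepl_mm)))
        return float(self.energy_ranges_mm[i])

    def range_index(self, range_mm: float) -> int:
        i = int(np.argmin(np.abs(self.energy_ranges_mm - range_mm)))
        if abs(self.energy_ranges_mm[i] - range_mm) > 1e-6:
            raise ValueError(f"range {range_mm} mm not in the machine table")
        return i

    def sigma_at(self, wepl_mm: np.ndarray) -> np.ndarray:
        return self.sigma0_mm + self.sigma_growth * np.asarray(wepl_mm, dtype=float)

    def in_table(self, range_mm: float) -> bool:
        return bool(np.any(np.abs(self.energy_ranges_mm - range_mm) <= 1e-6))

    @classmethod
    def from_yaml(cls, path: str) -> "MachineModel":
        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
        if "energy_ranges_mm" in cfg:
            cfg["energy_ranges_mm"] = np.asarray(cfg["energy_ranges_mm"], dtype=float)
        return cls(**cfg)

    def to_yaml(self, path: str) -> None:
        cfg = {
            "energy_ranges_mm": [float(r) for r in self.energy_ranges_mm],
            "sigma0_mm": self.sigma0_mm,
            "sigma_growth": self.sigma_growth,
            "ray_step_mm": self.ray_step_mm,
            "range_shifter_wepl_mm": self.range_shifter_wepl_mm,
            "lateral_cutoff_sigma": self.lateral_cutoff_sigma,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(cfg, fh)
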