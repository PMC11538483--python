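"""ROI margin expansions and the setup-margin split used for robust planning.

Margins follow the clinical convention of a Minkowski dilation: a voxel
joins the expanded ROI iff its center lies within the margin (Euclidean,
mm) of some source-voxel center.  The anisotropic variant supports the six
independent directional margins (+x, -x, +y, -y, +z, -z) produced by
Van Herk-style recipes; `split_margin` divides a total setup margin into
the part handed to the robust optimizer as a setup-error magnitude and the
remainder applied as a geometric target expansion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import distance_transform_edt

from .volumes import VoxelVolume

__all__ = ["MarginSpec", "expand_isotropic", "expand_anisotropic", "split_margin", "van_herk_margin"]


@dataclass(frozen=True)
class MarginSpec:
    """Per-direction margins in mm: (+x, -x, +y, -y, +z, -z)."""

    plus_x: float
    minus_x: float
    plus_y: float
    minus_y: float
    plus_z: float
    minus_z: float

    def __post_init__(self) -> None:
        if any(m < 0 for m in self.as_tuple()):
            raise ValueError("margins must be >= 0")

    @classmethod
    def isotropic(cls, m: float) -> "MarginSpec":
        return cls(m, m, m, m, m, m)

    def as_tuple(self) -> tuple[float, ...]:
        return (self.plus_x, self.minus_x, self.plus_y, self.minus_y, self.plus_z, self.minus_z)

    @property
    def min_margin(self) -> float:
        return min(self.as_tuple())

    def is_isotropic(self) -> bool:
        t = self.as_tuple()
        return all(abs(m - t[0]) < 1e-12 for m in t)

    def minus(self, m: float) -> "MarginSpec":
        return MarginSpec(*(x - m for x in self.as_tuple()))


def van_herk_margin(sigma_systematic_mm: float, sigma_random_mm: float,
                    alpha: float = 2.5, beta: float = 0.7) -> float:
    """Classic population margin recipe alpha*Sigma + beta*sigma (mm).

    The coefficients are inputs, not constants of nature: alpha=2.5 /
    beta=0.7 is the textbook photon CTV-to-PTV recipe and serves only as a
    default for generating plausible directional margins.
    """
    if sigma_systematic_mm < 0 or sigma_random_mm < 0:
        raise ValueError("sigmas must be >= 0")
    return alpha * sigma_systematic_mm + beta * sigma_random_mm


def _check_touches_edge(mask: np.ndarray, name: str = "expansion") -> None:
    axes = []
    for ax in range(3):
        sl = [slice(None)] * 3
        for end in (0, -1):
            sl[ax] = end
            if mask[tuple(sl)].any():
                axes.append("xyz"[ax])
                break
    if axes:
        raise ValueError(f"{name} exceeds the grid along axis/axes: {', '.join(axes)}")


def expand_isotropic(mask: VoxelVolume, margin_mm: float) -> VoxelVolume:
    """Minkowski dilation of a boolean ROI by a Euclidean ball (mm).

    Implemented by thresholding the exact Euclidean distance transform of
    the complement; contains the input for any margin >= 0.
    """
    if margin_mm < 0:
        raise ValueError("margin must be >= 0")
    src = mask.values.astype(bool)
    if not src.any():
        raise ValueError("cannot expand an empty mask")
    if margin_mm == 0:
        return mask.like(src.copy())
    dist = distance_transform_edt(~src, sampling=mask.spacing)
    out = dist <= margin_mm + 1e-9
    _check_touches_edge(out)
    return mask.like(out)


def expand_anisotropic(mask: VoxelVolume, margins: MarginSpec) -> VoxelVolume:
    """Dilation by the axis-aligned anisotropic element of a MarginSpec.

    The structuring element is the set of offsets d with
    sum_i (d_i / m_i(sign d_i))^2 <= 1, i.e. an ellipsoid whose semi-axis
    along each signed direction equals that direction's margin — the
    natural anisotropic generalization of the Euclidean ball, degenerating
    to `expand_isotropic` when all six margins agree.
    """
    if margins.is_isotropic():
        return expand_isotropic(mask, margins.plus_x)
    src = mask.values.astype(bool)
    if not src.any():
        raise ValueError("cannot expand an empty mask")

    # dilate via separable scaled distance: brute-force structuring element
    sp = np.asarray(mask.spacing)
    m = margins.as_tuple()
    reach = [max(m[2 * i], m[2 * i + 1]) for i in range(3)]
    half = [int(np.ceil(reach[i] / sp[i] + 1e-9)) for i in range(3)]
    offs = np.meshgrid(*[np.arange(-h, h + 1) for h in half], indexing="ij")
    d = [offs[i] * sp[i] for i in range(3)]

    def semi(i, di):
        pos, neg = m[2 * i], m[2 * i + 1]
        out = np.where(di >= 0, pos, neg)
        return np.where(out == 0, np.finfo(float).tiny, out)

    q = sum((d[i] / semi(i, d[i])) ** 2 for i in range(3))
    elem = q <= 1.0 + 1e-9

    from scipy.ndimage import binary_dilation

    out = binary_dilation(src, structure=elem)
    _check_touches_edge(out)
    return mask.like(out)


def split_margin(total: MarginSpec, optimizer_part_mm: float) -> tuple[MarginSpec, float]:
    """Split a total setup margin into (geometric expansion, optimizer setup error).

    The robust optimizer receives an isotropic setup-error magnitude
    (`optimizer_part_mm`); the remainder of each directional margin is
    applied as a geometric expansion of the target.  The pair reconstructs
    the total exactly: geometric + optimizer_part == total per direction.
    """
    if optimizer_part_mm < 0:
        raise ValueError("optimizer part must be >= 0")
    if optimizer_part_mm > total.min_margin + 1e-12:
        raise ValueError(
            f"optimizer part {optimizer_part_mm} mm exceeds the smallest "
            f"directional margin {total.min_margin} mm"
        )
    return total.minus(optimizer_part_mm), optimizer_part_mm
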