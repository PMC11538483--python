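"""Regular-grid scalar volumes (density or dose) with physical metadata.

A :class:`VoxelVolume` is the shared container for planning images, ROI
masks (boolean-valued) and dose distributions.  Axes are ordered (x, y, z)
with voxel-center world coordinates ``origin + index * spacing`` in mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk

__all__ = ["VoxelVolume", "save_volume", "load_volume"]


@dataclass
class VoxelVolume:
    """Scalar field on a regular 3-D grid.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Relative density (unitless), dose (Gy), or a boolean mask.
    spacing : 3-tuple of float
        Voxel spacing per axis in mm; strictly positive.
    origin : 3-tuple of float
        World coordinate (mm) of the center of voxel (0, 0, 0).
    """

    values: np.ndarray
    spacing: tuple[float, float, float] = (2.5, 2.5, 2.5)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError("values must be a 3-D array")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive on all axes")
        if self.values.dtype != bool and not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_cc(self) -> float:
        """Volume of one voxel in cm^3."""
        return float(np.prod(self.spacing)) / 1000.0

    def axis_coords(self, axis: int) -> np.ndarray:
        """World coordinates (mm) of voxel centers along one axis."""
        n = self.shape[axis]
        return self.origin[axis] + self.spacing[axis] * np.arange(n)

    def grid_coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Meshgrid (ij) of world coordinates, one array per axis."""
        ax = [self.axis_coords(i) for i in range(3)]
        return tuple(np.meshgrid(*ax, indexing="ij"))  # type: ignore[return-value]

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Map world coordinates (..., 3) to fractional voxel indices."""
        pts = np.asarray(points, dtype=float)
        return (pts - np.asarray(self.origin)) / np.asarray(self.spacing)

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        idx = np.asarray(idx, dtype=float)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def like(self, values: np.ndarray) -> "VoxelVolume":
        """New volume with the same grid and different values."""
        return VoxelVolume(values, self.spacing, self.origin)

    def zeros_like(self, dtype=np.float64) -> "VoxelVolume":
        return self.like(np.zeros(self.shape, dtype=dtype))

    def same_grid(self, other: "VoxelVolume", atol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )

    def sample(self, points: np.ndarray, order: int = 1, mode: str = "constant") -> np.ndarray:
        """Interpolate the field at world points (..., 3).

        Trilinear by default; points outside the grid return 0 unless
        ``mode`` selects another boundary extension (e.g. 'nearest').
        """
        from scipy.ndimage import map_coordinates

        idx = self.world_to_index(points)
        flat = idx.reshape(-1, 3).T
        vals = map_coordinates(
            self.values.astype(float), flat, order=order, mode=mode, cval=0.0
        )
        return vals.reshape(np.asarray(points).shape[:-1])


def save_volume(vol: VoxelVolume, path: str) -> None:
    """Write a volume as MetaImage/NIfTI (by extension) via SimpleITK.

    Array axes (x, y, z) are transposed to ITK's (z, y, x) buffer order so
    spacing/origin metadata round-trip.
    """
    img = sitk.GetImageFromArray(np.ascontiguousarray(vol.values.T.astype(np.float32)))
    img.SetSpacing(vol.spacing)
    img.SetOrigin(vol.origin)
    sitk.WriteImage(img, path)


def load_volume(path: str) -> VoxelVolume:
    img = sitk.ReadImage(path)
    arr = sitk.GetArrayFromImage(img).T
    return VoxelVolume(np.asarray(arr), tuple(img.GetSpacing()), tuple(img.GetOrigin()))
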