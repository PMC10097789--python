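"""Binarized voxel volumes (bone = True, marrow = False).

The in-memory axis order is (x, y, z); world coordinates are millimetres
with ``origin_mm`` at the centre of voxel (0, 0, 0).  Voxel size is stored
in micrometres, the unit micro-CT vendors report.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class BinaryVolume:
    """A 3D boolean voxel grid plus physical metadata.

    Parameters
    ----------
    data : ndarray of bool, shape (nx, ny, nz)
        Bone phase is ``True``.
    voxel_size_um : float
        Isotropic voxel edge length in micrometres.
    origin_mm : ndarray, shape (3,)
        World position (mm) of the centre of voxel (0, 0, 0).
    """

    data: np.ndarray
    voxel_size_um: float
    origin_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError("volume data must be a non-empty 3D array")
        if not self.voxel_size_um > 0:
            raise ValueError("voxel_size_um must be positive")
        self.origin_mm = np.asarray(self.origin_mm, dtype=float).reshape(3)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_size_mm(self) -> float:
        return self.voxel_size_um / 1000.0

    @property
    def bvtv(self) -> float:
        """Bone volume fraction of the whole grid (bone voxels / voxels)."""
        return float(np.count_nonzero(self.data)) / self.data.size

    def extent_mm(self) -> np.ndarray:
        """(lo, hi) world bounds (mm) of the voxel-centre lattice."""
        hi = self.origin_mm + (np.array(self.shape) - 1) * self.voxel_size_mm
        return np.stack([self.origin_mm, hi])

    def world_to_voxel(self, points_mm: np.ndarray) -> np.ndarray:
        """Map world coordinates (mm) to fractional voxel indices."""
        pts = np.asarray(points_mm, dtype=float)
        return (pts - self.origin_mm) / self.voxel_size_mm

    def contains_point(self, point_mm: np.ndarray) -> bool:
        v = self.world_to_voxel(point_mm)
        return bool(np.all(v >= -0.5) and np.all(v <= np.array(self.shape) - 0.5))
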