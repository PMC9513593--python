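"""Axis-aligned voxel grid, centred on the scanner axis.

Coordinates are right-handed, origin at the scanner centre, z along
the scanner axis, voxel-centre convention: voxel ``(i, j, k)`` has its
centre at ``origin + (i+0.5, j+0.5, k+0.5) * voxel_size``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Grid"]


@dataclass(frozen=True)
class Grid:
    shape: tuple  # (nx, ny, nz)
    voxel_size: float = 4.0
    center: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if len(self.shape) != 3 or any(s < 1 for s in self.shape):
            raise ValueError("grid shape must be three positive integers")
        if self.voxel_size <= 0:
            raise ValueError("voxel size must be positive")

    @property
    def extent(self) -> np.ndarray:
        return np.asarray(self.shape, dtype=float) * self.voxel_size

    @property
    def origin(self) -> np.ndarray:
        """Position of the low corner of voxel (0, 0, 0)."""
        return np.asarray(self.center, dtype=float) - self.extent / 2.0

    @property
    def voxel_volume_ml(self) -> float:
        return self.voxel_size**3 / 1000.0

    def voxel_centers(self):
        """Meshgrid (x, y, z) arrays of voxel-centre coordinates."""
        o = self.origin
        ax = [o[d] + (np.arange(self.shape[d]) + 0.5) * self.voxel_size for d in range(3)]
        return np.meshgrid(*ax, indexing="ij")

    def contains_box(self, lo, hi) -> bool:
        """Whether an axis-aligned box [lo, hi] lies inside the grid."""
        o = self.origin
        e = o + self.extent
        return bool(np.all(np.asarray(lo) >= o - 1e-9) and np.all(np.asarray(hi) <= e + 1e-9))
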