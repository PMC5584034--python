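"""3D attenuation volumes on regular grids."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["VolumeImage"]


@dataclass
class VolumeImage:
    """Scalar attenuation grid.

    ``values[i, j, k]`` is the linear attenuation coefficient (1/mm) of
    the voxel whose center is at
    ``origin + (i + 0.5, j + 0.5, k + 0.5) * voxel_size`` — grids are
    cell-centered and ``origin`` is the outer corner of voxel (0,0,0).
    """

    values: np.ndarray
    voxel_size: tuple[float, float, float]
    origin: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError("volume values must be a 3D array")
        vs = np.broadcast_to(np.asarray(self.voxel_size, dtype=float), (3,))
        self.voxel_size = tuple(float(v) for v in vs)
        self.origin = tuple(float(v) for v in np.asarray(self.origin, dtype=float))
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel size must be positive")

    # ------------------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def extent(self) -> tuple[float, float, float]:
        return tuple(n * v for n, v in zip(self.shape, self.voxel_size))

    def axis_centers(self, axis: int) -> np.ndarray:
        """Physical coordinates (mm) of voxel centers along one axis."""
        n = self.shape[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * self.voxel_size[axis]

    def copy(self, values: np.ndarray | None = None) -> "VolumeImage":
        vals = self.values.copy() if values is None else np.asarray(values, float)
        return VolumeImage(vals, self.voxel_size, self.origin)

    def like(self, values: np.ndarray) -> "VolumeImage":
        """New volume with the same grid and the given values."""
        if values.shape != self.values.shape:
            raise ValueError("value array does not match the grid shape")
        return VolumeImage(np.asarray(values, float), self.voxel_size, self.origin)

    @classmethod
    def zeros(
        cls,
        shape: tuple[int, int, int],
        voxel_size,
        origin=None,
    ) -> "VolumeImage":
        """Empty centered grid (origin chosen so the grid is centered at 0)."""
        vs = np.broadcast_to(np.asarray(voxel_size, float), (3,))
        if origin is None:
            origin = tuple(-n * v / 2.0 for n, v in zip(shape, vs))
        return cls(np.zeros(shape), tuple(vs), origin)
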