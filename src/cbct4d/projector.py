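"""Ray-driven cone-beam forward projection and its exact adjoint.

``forward_project`` evaluates the system matrix ``A`` whose entries are
the intersection lengths of each source-to-detector-element ray with the
voxel grid, so a projection element holds the line integral
``y_i = sum_j A_ij mu_j`` (dimensionless).  ``back_project`` applies the
transpose of the same matrix.  ``counts_from_line_integrals`` maps line
integrals to expected photon counts ``n_i = n0 * exp(-y_i)`` of the
monochromatic transmission model, optionally with Poisson noise.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import _kernels
from .geometry import ScanGeometry
from .volume import VolumeImage

__all__ = [
    "ProjectionSet",
    "forward_project",
    "back_project",
    "counts_from_line_integrals",
]


@dataclass
class ProjectionSet:
    """Stack of 2D line-integral frames, one per gantry angle.

    ``frames`` has shape ``(n_angles, detector_rows, detector_cols)``;
    ``n0`` is the (constant) source photon fluence per detector element
    used when converting to counts.
    """

    frames: np.ndarray
    angles: np.ndarray
    timestamps: np.ndarray
    n0: float = 1e5

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        self.angles = np.asarray(self.angles, dtype=float)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (n_angles, rows, cols)")
        if len(self.angles) != len(self.frames) or len(self.timestamps) != len(
            self.frames
        ):
            raise ValueError("angles/timestamps must match the number of frames")

    @property
    def n_angles(self) -> int:
        return len(self.frames)

    @property
    def element_count(self) -> int:
        """Total number of projection elements M."""
        return int(self.frames.size)

    def subset(self, indices) -> "ProjectionSet":
        idx = np.asarray(indices)
        return replace(
            self,
            frames=self.frames[idx],
            angles=self.angles[idx],
            timestamps=self.timestamps[idx],
        )

    def validate_against(self, geometry: ScanGeometry) -> None:
        if self.frames.shape[1:] != (geometry.detector_rows, geometry.detector_cols):
            raise ValueError(
                f"frame shape {self.frames.shape[1:]} does not match detector "
                f"grid {(geometry.detector_rows, geometry.detector_cols)}"
            )


def _frame_geometry(geometry: ScanGeometry, angle: float):
    src = geometry.source_position(angle)
    org = geometry.detector_origin(angle)
    u, v = geometry.detector_axes(angle)
    return src, org, u, v


def forward_project(
    volume: VolumeImage,
    geometry: ScanGeometry,
    angle_subset: np.ndarray | None = None,
    out: np.ndarray | None = None,
) -> ProjectionSet:
    """Noiseless line integrals of ``volume`` for all (or a subset of) angles.

    Rays run from the source to the center of each detector element and
    integrate over the voxels they intersect (Siddon traversal); rays
    missing the grid yield 0.
    """
    angles = geometry.angles
    times = geometry.timestamps
    if angle_subset is not None:
        angles = angles[np.asarray(angle_subset)]
        times = times[np.asarray(angle_subset)]
    vol = np.ascontiguousarray(volume.values)
    ox, oy, oz = volume.origin
    vx, vy, vz = volume.voxel_size
    if out is None:
        out = np.empty(
            (len(angles), geometry.detector_rows, geometry.detector_cols), dtype=np.float64
        )
    for i, ang in enumerate(angles):
        src, org, u, v = _frame_geometry(geometry, ang)
        _kernels.siddon_forward_frame(
            vol, ox, oy, oz, vx, vy, vz,
            src[0], src[1], src[2],
            org[0], org[1], org[2], u[0], u[1], u[2], v[0], v[1], v[2],
            geometry.pitch_u, geometry.pitch_v, out[i],
        )
    return ProjectionSet(out, angles, times)


def back_project(
    projections: ProjectionSet,
    geometry: ScanGeometry,
    grid: VolumeImage,
) -> VolumeImage:
    """Exact adjoint of :func:`forward_project` onto the grid of ``grid``."""
    projections.validate_against(geometry)
    vol = np.zeros(grid.shape, dtype=np.float64)
    ox, oy, oz = grid.origin
    vx, vy, vz = grid.voxel_size
    for frame, ang in zip(projections.frames, projections.angles):
        src, org, u, v = _frame_geometry(geometry, ang)
        _kernels.siddon_back_frame(
            vol, ox, oy, oz, vx, vy, vz,
            src[0], src[1], src[2],
            org[0], org[1], org[2], u[0], u[1], u[2], v[0], v[1], v[2],
            geometry.pitch_u, geometry.pitch_v, np.ascontiguousarray(frame),
        )
    return grid.like(vol)


def counts_from_line_integrals(
    projections: ProjectionSet,
    n0: float | None = None,
    noisy: bool = False,
    seed: int | None = None,
) -> np.ndarray:
    """Expected (or Poisson-sampled) photon counts ``n = n0 exp(-y)``."""
    if n0 is None:
        n0 = projections.n0
    if n0 <= 0:
        raise ValueError("n0 must be positive")
    y = projections.frames
    if not np.all(np.isfinite(y)) or np.any(y < 0):
        raise ValueError("line integrals must be finite and nonnegative")
    mean = n0 * np.exp(-y)
    if not noisy:
        return mean
    rng = np.random.default_rng(seed)
    return rng.poisson(mean).astype(np.float64)
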