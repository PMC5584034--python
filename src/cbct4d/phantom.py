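"""Time-dependent digital phantom: an elliptic cylinder with a moving air sphere.

The phantom emulates a pelvis-scale body (uniform elliptic-cylindrical
cross-section) containing a 3 cm air sphere that translates along the
rotation axis at constant speed — a minimal model of non-periodic bulk
motion such as travelling rectal gas.  Two standard motion presets are
provided: the sphere crosses its 3 cm path during the full 60 s rotation
(0.5 mm/s), or during the central half of the scan, while the source
sweeps from the 90-degree to the 270-degree position (1.0 mm/s).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .volume import VolumeImage

__all__ = [
    "PhantomSpec",
    "phantom_volume",
    "sphere_center",
    "occupancy_edge_oracle",
    "phantom_preset",
]


class PhantomError(ValueError):
    """Raised for self-inconsistent phantom configurations."""


@dataclass(frozen=True)
class PhantomSpec:
    """Moving-sphere phantom description (lengths in mm, times in s)."""

    ellipse_semi_axis_x: float = 110.0
    ellipse_semi_axis_y: float = 80.0
    cylinder_length: float = 1000.0  # effectively unbounded in z
    body_mu: float = 0.02  # 1/mm, soft-tissue scale
    sphere_diameter: float = 30.0
    sphere_mu: float = 0.0  # air
    motion_extent: float = 30.0  # travel along z
    motion_start_time: float = 0.0
    motion_end_time: float = 60.0
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    grid_dims: tuple[int, int, int] = (256, 256, 90)

    def __post_init__(self) -> None:
        if self.motion_end_time <= self.motion_start_time:
            raise PhantomError("motion_end_time must exceed motion_start_time")
        if self.sphere_mu < 0 or self.body_mu <= self.sphere_mu:
            raise PhantomError("need body_mu > sphere_mu >= 0")
        r = self.sphere_diameter / 2.0
        if (
            r > self.ellipse_semi_axis_x
            or r > self.ellipse_semi_axis_y
            or self.motion_extent / 2.0 + r > self.cylinder_length / 2.0
        ):
            raise PhantomError("sphere must stay inside the cylinder at all times")

    @property
    def sphere_radius(self) -> float:
        return self.sphere_diameter / 2.0

    @property
    def speed(self) -> float:
        """Sphere speed during motion, mm/s."""
        return self.motion_extent / (self.motion_end_time - self.motion_start_time)

    def grid(self) -> VolumeImage:
        return VolumeImage.zeros(self.grid_dims, self.voxel_size)


def sphere_center(spec: PhantomSpec, time: float) -> float:
    """Axial (z) sphere-center position at ``time``, in mm.

    The path runs from ``-motion_extent/2`` to ``+motion_extent/2`` at
    constant speed; before/after the motion interval the sphere dwells
    at the corresponding endpoint.
    """
    t0, t1 = spec.motion_start_time, spec.motion_end_time
    frac = np.clip((time - t0) / (t1 - t0), 0.0, 1.0)
    return float((frac - 0.5) * spec.motion_extent)


def phantom_volume(spec: PhantomSpec, time: float) -> VolumeImage:
    """Voxelize the phantom at acquisition time ``time`` (seconds).

    Center-sampled voxelization: a voxel takes ``sphere_mu`` iff its
    center lies inside the sphere, ``body_mu`` iff inside the elliptic
    cylinder, else 0.
    """
    grid = spec.grid()
    x = grid.axis_centers(0)
    y = grid.axis_centers(1)
    z = grid.axis_centers(2)
    X = x[:, None] / spec.ellipse_semi_axis_x
    Y = y[None, :] / spec.ellipse_semi_axis_y
    body2d = (X**2 + Y**2) <= 1.0
    inside_z = np.abs(z) <= spec.cylinder_length / 2.0
    vol = spec.body_mu * (body2d[:, :, None] & inside_z[None, None, :])

    zc = sphere_center(spec, time)
    r2 = (
        (x[:, None, None]) ** 2
        + (y[None, :, None]) ** 2
        + (z[None, None, :] - zc) ** 2
    )
    vol = np.where(r2 <= spec.sphere_radius**2, spec.sphere_mu, vol)
    return grid.like(vol)


def occupancy_edge_oracle(
    spec: PhantomSpec, n_samples: int = 2001
) -> tuple[np.ndarray, np.ndarray, float]:
    """Analytic time-averaged sphere occupancy on the central axis.

    For uniform motion over an extent ``L``, the fraction of the motion
    during which an axial position ``z`` lies inside the sphere is the
    overlap of the interval ``(z - R, z + R)`` with the path of the
    center, divided by ``L`` — a trapezoid whose ramps have width
    ``min(L, 2R)``.  Its 10-90% edge width is therefore
    ``0.8 * min(L, 2R)`` (for a static sphere the edge is a step of
    width 0).  This is the motion-blur profile an ideal time-averaging
    reconstruction of the moving cavity would show.

    Returns ``(z, occupancy, width_10_90_mm)``.
    """
    R = spec.sphere_radius
    L = spec.motion_extent
    lo, hi = -L / 2.0, L / 2.0
    z = np.linspace(lo - 2 * R, hi + 2 * R, n_samples)
    if L == 0:
        occ = (np.abs(z) < R).astype(float)
        width = 0.0
    else:
        overlap = np.minimum(z + R, hi) - np.maximum(z - R, lo)
        occ = np.clip(overlap / L, 0.0, 1.0)
        width = 0.8 * min(L, 2 * R)
    return z, occ, float(width)


def phantom_preset(
    motion: str = "3cm60s",
    scan_duration: float = 60.0,
    **overrides,
) -> PhantomSpec:
    """Standard moving-sphere presets.

    ``"3cm60s"``: 3 cm travel across the whole 60 s rotation (0.5 mm/s).
    ``"3cm30s"``: 3 cm travel during the central 30 s of the scan, i.e.
    while the source sweeps from 90 to 270 degrees at 6 deg/s (1.0 mm/s).
    ``"static"``: sphere parked mid-path.
    """
    if motion == "3cm60s":
        spec = PhantomSpec(motion_start_time=0.0, motion_end_time=scan_duration)
    elif motion == "3cm30s":
        spec = PhantomSpec(
            motion_start_time=scan_duration / 4.0,
            motion_end_time=3.0 * scan_duration / 4.0,
        )
    elif motion == "static":
        # zero extent is disallowed only implicitly; keep the sphere mid-path
        spec = PhantomSpec(
            motion_extent=1e-9, motion_start_time=0.0, motion_end_time=scan_duration
        )
    else:
        raise PhantomError(f"unknown phantom preset {motion!r}")
    if overrides:
        spec = replace(spec, **overrides)
    return spec
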