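"""Continuous-acquisition simulation of the moving-sphere phantom.

Each projection frame sees the phantom frozen at that frame's
acquisition timestamp, which models a continuously moving object
sampled by a rotating source (intra-frame motion is neglected, as for a
pulsed kV exposure).  Line integrals are noiseless by default; Poisson
counts can be drawn downstream via
:func:`cbct4d.projector.counts_from_line_integrals`.
"""

from __future__ import annotations

import numpy as np

from .geometry import ScanGeometry
from .phantom import PhantomSpec, phantom_volume, sphere_center
from .projector import ProjectionSet, forward_project
from .volume import VolumeImage

__all__ = ["simulate_scan", "ground_truth_volume"]


def ground_truth_volume(spec: PhantomSpec, time: float) -> VolumeImage:
    """Voxelized phantom at ``time`` (reference for image metrics)."""
    return phantom_volume(spec, time)


def _background(spec: PhantomSpec, grid: VolumeImage) -> np.ndarray:
    """Sphere-free elliptic cylinder on the grid."""
    x = grid.axis_centers(0)
    y = grid.axis_centers(1)
    z = grid.axis_centers(2)
    X = x[:, None] / spec.ellipse_semi_axis_x
    Y = y[None, :] / spec.ellipse_semi_axis_y
    body2d = (X**2 + Y**2) <= 1.0
    inside_z = np.abs(z) <= spec.cylinder_length / 2.0
    return spec.body_mu * (body2d[:, :, None] & inside_z[None, None, :])


def simulate_scan(
    spec: PhantomSpec,
    geometry: ScanGeometry,
    n0: float = 1e5,
) -> ProjectionSet:
    """Simulate the full cone-beam acquisition of the moving phantom.

    Returns the stack of line-integral frames, one per gantry angle, in
    time order.  Deterministic (noiseless).
    """
    grid = spec.grid()
    body = _background(spec, grid)
    x = grid.axis_centers(0)
    y = grid.axis_centers(1)
    z = grid.axis_centers(2)
    r2_xy = x[:, None] ** 2 + y[None, :] ** 2

    frames = np.empty(
        (geometry.n_angles, geometry.detector_rows, geometry.detector_cols),
        dtype=np.float64,
    )
    work = body.copy()
    vol = grid.like(work)
    prev_slab = (0, 0)
    for i, t in enumerate(geometry.timestamps):
        k0, k1 = prev_slab
        work[:, :, k0:k1] = body[:, :, k0:k1]
        prev_slab = _stamp_sphere(work, spec, r2_xy, z, sphere_center(spec, t))
        forward_project(vol, geometry, angle_subset=[i], out=frames[i : i + 1])
    return ProjectionSet(
        frames, geometry.angles.copy(), geometry.timestamps.copy(), n0=n0
    )


def _stamp_sphere(vol, spec, r2_xy, z, zc) -> tuple[int, int]:
    """Write the sphere into ``vol``; returns the touched z-slab."""
    R = spec.sphere_radius
    k = np.nonzero(np.abs(z - zc) <= R)[0]
    if k.size == 0:
        return (0, 0)
    k0, k1 = int(k[0]), int(k[-1]) + 1
    for kk in range(k0, k1):
        mask = r2_xy <= R**2 - (z[kk] - zc) ** 2
        vol[:, :, kk][mask] = spec.sphere_mu
    return (k0, k1)
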