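"""Extension of laterally truncated (offset-detector) projections.

An offset flat panel (medium field-of-view acquisition) truncates every
projection on one side.  Before TV-regularized reconstruction the
projections are extended in three steps:

1. reconstruct the whole object by FDK from all 360-degree truncated
   projections (with redundancy weighting for the offset panel);
2. reproject that volume onto a widened virtual detector;
3. mosaic: keep the measured values wherever the real panel covers,
   fill the peripheral band with the reprojected values (a short linear
   cross-fade hides the seam).

The widened panel extends the real one by ``ceil(offset / pitch)``
columns on each side, which turns a 512-wide panel offset by 115 mm at
0.8 mm pitch into an 800-wide virtual panel.
"""

from __future__ import annotations

import numpy as np

from .fdk import reconstruct_fdk
from .geometry import ScanGeometry
from .projector import ProjectionSet, forward_project
from .volume import VolumeImage

__all__ = ["extend_projections", "extended_geometry"]


def extended_geometry(
    geometry: ScanGeometry, extended_cols: int | None = None
) -> ScanGeometry:
    """Virtual widened panel geometry for the extended projections.

    The virtual panel keeps the real panel's center and column lattice
    (so measured columns map one-to-one onto virtual columns) and adds
    ``ceil(offset / pitch)`` columns on each side, enough to cover the
    formerly truncated side of the object in every view.
    """
    if extended_cols is None:
        pad = int(np.ceil(abs(geometry.lateral_offset) / geometry.pitch_u))
        extended_cols = geometry.detector_cols + 2 * pad
    return geometry.with_detector(detector_cols=extended_cols)


def extend_projections(
    truncated: ProjectionSet,
    geometry: ScanGeometry,
    full_grid: VolumeImage,
    extended_cols: int | None = None,
    seam_columns: int = 5,
    window: str = "hann",
) -> tuple[ProjectionSet, ScanGeometry]:
    """Produce widened mosaic projections from a truncated 360-degree scan.

    Returns the extended projection set together with its virtual-panel
    geometry.  Measured columns are passed through
    bit-for-bit except inside the ``seam_columns``-wide cross-fade at
    the real/virtual boundary; reprojected values fill the rest and are
    clipped to be nonnegative.
    """
    truncated.validate_against(geometry)
    if geometry.angular_range < 360.0 - 1e-6:
        raise ValueError("projection extension requires full 360-degree coverage")

    # step 1: whole-object FDK from the truncated data
    interim = reconstruct_fdk(
        truncated, geometry, full_grid, window=window, offset_weighting=True
    )

    # step 2: reprojection onto the widened virtual panel
    geo_ext = extended_geometry(geometry, extended_cols)
    virtual = forward_project(interim, geo_ext)
    np.maximum(virtual.frames, 0.0, out=virtual.frames)

    # step 3: mosaic of real and reproduced columns
    u_real = geometry.u_coords()
    u_ext = geo_ext.u_coords()
    # map real columns onto virtual columns (same pitch, shifted center)
    col0 = int(np.rint((u_real[0] - u_ext[0]) / geo_ext.pitch_u))
    ncols = geometry.detector_cols
    if col0 < 0 or col0 + ncols > geo_ext.detector_cols:
        raise ValueError("extended panel does not cover the real panel")
    if abs((u_real[0] - u_ext[0]) / geo_ext.pitch_u - col0) > 1e-6:
        raise ValueError("real and virtual panels are not column-aligned")

    frames = virtual.frames
    frames[:, :, col0 : col0 + ncols] = truncated.frames
    # cross-fade the virtual side of each seam toward the measured edge
    for edge, inward in ((col0 - 1, -1), (col0 + ncols, +1)):
        ref_col = edge - inward  # nearest measured column
        for k in range(seam_columns):
            c = edge + inward * k
            if c < 0 or c >= geo_ext.detector_cols:
                break
            w = (k + 1) / (seam_columns + 1)
            frames[:, :, c] = (1 - w) * truncated.frames[
                :, :, ref_col - col0
            ] + w * frames[:, :, c]

    out = ProjectionSet(
        frames, truncated.angles.copy(), truncated.timestamps.copy(), truncated.n0
    )
    return out, geo_ext
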