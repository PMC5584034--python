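"""Cone-beam scan geometry.

Conventions (used throughout the package):

* right-handed coordinates, ``z`` is the rotation axis (cranio-caudal),
  the isocenter is the origin;
* the gantry angle is measured from the ``+y`` source position, so at
  angle ``theta`` (degrees) the source sits at
  ``SAD * (sin(theta), cos(theta), 0)``;
* the flat-panel detector is perpendicular to the central ray, its
  in-plane axis is ``u = (cos(theta), -sin(theta), 0)`` and its axial
  axis is ``v = (0, 0, 1)``;
* a lateral (cross-line) detector offset shifts the panel along ``+u``,
  measured in mm at the detector plane.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["ScanGeometry", "make_geometry", "GEOMETRY_PRESETS"]

#: Default distances of a linac-mounted kV imaging chain (Elekta XVI class).
DEFAULT_SAD = 1000.0
DEFAULT_SDD = 1536.0
DEFAULT_PITCH = 0.8

#: Lateral panel offsets (mm at the detector) of the S / M / L collimator
#: field-of-view modes.
FOV_OFFSETS = {"S": 0.0, "M": 115.0, "L": 190.0}


class GeometryError(ValueError):
    """Raised for inconsistent scan-geometry configurations."""


@dataclass(frozen=True)
class ScanGeometry:
    """Circular cone-beam acquisition description.

    Parameters
    ----------
    sad, sdd
        Source-to-axis and source-to-detector distances in mm.
    detector_rows, detector_cols
        Panel grid size; rows run along ``v`` (axial), columns along
        ``u`` (cross-line).
    pitch_u, pitch_v
        Detector element pitch in mm.
    lateral_offset
        Cross-line panel shift in mm at the detector (0 for the
        symmetric S FOV, 115 for M, 190 for L).
    angles
        Gantry angles in degrees, one per projection frame.
    timestamps
        Acquisition time of each frame in seconds, strictly increasing.
    """

    sad: float
    sdd: float
    detector_rows: int
    detector_cols: int
    pitch_u: float
    pitch_v: float
    lateral_offset: float
    angles: np.ndarray
    timestamps: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "angles", np.asarray(self.angles, dtype=float))
        object.__setattr__(self, "timestamps", np.asarray(self.timestamps, dtype=float))
        if not (self.sdd > self.sad > 0):
            raise GeometryError(
                f"need SDD > SAD > 0, got SAD={self.sad}, SDD={self.sdd}"
            )
        if self.pitch_u <= 0 or self.pitch_v <= 0:
            raise GeometryError("detector pitch must be positive")
        if self.detector_rows < 1 or self.detector_cols < 1:
            raise GeometryError("detector grid must be at least 1x1")
        if self.angles.shape != self.timestamps.shape:
            raise GeometryError("angles and timestamps must have equal length")
        if self.angles.size and np.any(np.diff(self.timestamps) <= 0):
            raise GeometryError("timestamps must be strictly increasing")

    # ------------------------------------------------------------------
    @property
    def n_angles(self) -> int:
        return int(self.angles.size)

    @property
    def magnification(self) -> float:
        return self.sdd / self.sad

    @property
    def rotation_speed(self) -> float:
        """Mean gantry speed in degrees/second."""
        span_t = self.timestamps[-1] - self.timestamps[0]
        span_a = self.angles[-1] - self.angles[0]
        return float(span_a / span_t) if span_t > 0 else 0.0

    @property
    def duration(self) -> float:
        """Total scan time in seconds (including one trailing frame interval)."""
        if self.n_angles < 2:
            return 0.0
        dt = self.timestamps[1] - self.timestamps[0]
        return float(self.timestamps[-1] - self.timestamps[0] + dt)

    @property
    def angular_range(self) -> float:
        """Covered gantry arc in degrees (including one frame step)."""
        if self.n_angles < 2:
            return 0.0
        da = self.angles[1] - self.angles[0]
        return float(self.angles[-1] - self.angles[0] + da)

    # ------------------------------------------------------------------
    def source_position(self, angle_deg: float) -> np.ndarray:
        th = np.deg2rad(angle_deg)
        return self.sad * np.array([np.sin(th), np.cos(th), 0.0])

    def detector_axes(self, angle_deg: float) -> tuple[np.ndarray, np.ndarray]:
        th = np.deg2rad(angle_deg)
        u = np.array([np.cos(th), -np.sin(th), 0.0])
        v = np.array([0.0, 0.0, 1.0])
        return u, v

    def detector_origin(self, angle_deg: float) -> np.ndarray:
        """Center of detector element (0, 0) in mm."""
        th = np.deg2rad(angle_deg)
        center = -(self.sdd - self.sad) * np.array([np.sin(th), np.cos(th), 0.0])
        u, v = self.detector_axes(angle_deg)
        u0 = self.lateral_offset - (self.detector_cols - 1) / 2.0 * self.pitch_u
        v0 = -(self.detector_rows - 1) / 2.0 * self.pitch_v
        return center + u0 * u + v0 * v

    def u_coords(self) -> np.ndarray:
        """Cross-line element coordinates in mm at the detector plane."""
        c = np.arange(self.detector_cols)
        return (c - (self.detector_cols - 1) / 2.0) * self.pitch_u + self.lateral_offset

    def v_coords(self) -> np.ndarray:
        r = np.arange(self.detector_rows)
        return (r - (self.detector_rows - 1) / 2.0) * self.pitch_v

    def subset(self, indices: np.ndarray) -> "ScanGeometry":
        """Geometry restricted to a subset of frames."""
        idx = np.asarray(indices)
        return replace(self, angles=self.angles[idx], timestamps=self.timestamps[idx])

    def with_detector(
        self,
        detector_cols: int | None = None,
        detector_rows: int | None = None,
        lateral_offset: float | None = None,
    ) -> "ScanGeometry":
        kw = {}
        if detector_cols is not None:
            kw["detector_cols"] = detector_cols
        if detector_rows is not None:
            kw["detector_rows"] = detector_rows
        if lateral_offset is not None:
            kw["lateral_offset"] = lateral_offset
        return replace(self, **kw)


# ----------------------------------------------------------------------
_FIELD_ALIASES = {
    "source_to_axis_distance": "sad",
    "source_to_detector_distance": "sdd",
    "detector_lateral_offset": "lateral_offset",
    "detector_pitch": "pitch",
}


def make_geometry(
    config: dict | None = None,
    *,
    n_angles: int = 360,
    angular_range: float = 360.0,
    duration: float = 60.0,
    fov: str = "S",
    **kwargs,
) -> ScanGeometry:
    """Build a :class:`ScanGeometry` from structured parameters.

    Parameters may be given as a config mapping (long external field
    names such as ``source_to_axis_distance`` are accepted) and/or as
    keyword arguments.  Angle/timestamp schedules may be passed
    explicitly (``angles``, ``timestamps``) or generated from
    ``n_angles`` equally spaced frames over ``angular_range`` degrees
    acquired in ``duration`` seconds.

    The default preset is a full 360-degree scan of 360 one-degree
    frames in 60 s (6 deg/s gantry speed) on a 512x512 panel of 0.8 mm
    pitch; ``fov`` selects the lateral panel offset ("S", "M" or "L").
    """
    params: dict = {}
    if config:
        params.update(config)
    params.update(kwargs)
    for long, short in _FIELD_ALIASES.items():
        if long in params:
            params[short] = params.pop(long)

    n_angles = int(params.pop("n_angles", n_angles))
    angular_range = float(params.pop("angular_range", angular_range))
    duration = float(params.pop("duration", duration))
    fov = params.pop("fov", fov)
    if fov not in FOV_OFFSETS:
        raise GeometryError(f"unknown FOV mode {fov!r}; expected one of S, M, L")

    pitch = params.pop("pitch", DEFAULT_PITCH)
    angles = params.pop("angles", None)
    timestamps = params.pop("timestamps", None)
    if angles is None:
        angles = np.arange(n_angles) * (angular_range / n_angles)
    angles = np.asarray(angles, dtype=float)
    if timestamps is None:
        timestamps = np.arange(len(angles)) * (duration / len(angles))
    timestamps = np.asarray(timestamps, dtype=float)

    geo = ScanGeometry(
        sad=float(params.pop("sad", DEFAULT_SAD)),
        sdd=float(params.pop("sdd", DEFAULT_SDD)),
        detector_rows=int(params.pop("detector_rows", 512)),
        detector_cols=int(params.pop("detector_cols", 512)),
        pitch_u=float(params.pop("pitch_u", pitch)),
        pitch_v=float(params.pop("pitch_v", pitch)),
        lateral_offset=float(params.pop("lateral_offset", FOV_OFFSETS[fov])),
        angles=angles,
        timestamps=timestamps,
    )
    if params:
        raise GeometryError(f"unknown geometry parameters: {sorted(params)}")
    return geo


GEOMETRY_PRESETS = {
    "S": dict(fov="S"),
    "M": dict(fov="M"),
    "L": dict(fov="L"),
}
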