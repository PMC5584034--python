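"""Quantitative image metrics.

* ``penumbral_width`` — the 10-90% width of the (inverted, normalized)
  axial profile of a moving air cavity; the blur of this edge is the
  temporal-resolution surrogate for a sphere translating along the
  rotation axis.
* ``roi_consistency_rmse`` — RMSE of circular-ROI mean pixel values
  across phases, normalized by the ROI mean of a reference image, in
  percent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume import VolumeImage

__all__ = [
    "PenumbraResult",
    "penumbral_width",
    "axial_profile",
    "RoiSpec",
    "roi_mask",
    "roi_mean",
    "roi_consistency_rmse",
    "volume_rmse",
]


@dataclass
class PenumbraResult:
    """10-90% penumbral width of an air cavity along the central axis."""

    width_mm: float
    width_left_mm: float
    width_right_mm: float
    background: float
    z: np.ndarray
    profile: np.ndarray  # raw attenuation profile
    inverse: np.ndarray  # inverted, normalized to [0, 1]


def axial_profile(volume: VolumeImage) -> tuple[np.ndarray, np.ndarray]:
    """Attenuation profile along the rotation axis at x = y = 0.

    The central axis of a centered even-sized grid runs along the corner
    between four voxel columns; the profile is their bilinear value at
    (0, 0), i.e. the mean of the adjacent columns.
    """
    x = volume.axis_centers(0)
    y = volume.axis_centers(1)
    ix = np.argsort(np.abs(x))[:2]
    iy = np.argsort(np.abs(y))[:2]
    # use 1 column if the axis passes through voxel centers, else 2
    ix = ix[: 1 if abs(x[ix[0]]) < 1e-9 else 2]
    iy = iy[: 1 if abs(y[iy[0]]) < 1e-9 else 2]
    prof = volume.values[np.ix_(ix, iy)].mean(axis=(0, 1))
    return volume.axis_centers(2), prof


def _interp_crossing(z, q, i_lo, i_hi, level):
    """Sub-sample position where q crosses ``level`` between two samples."""
    q0, q1 = q[i_lo], q[i_hi]
    if q1 == q0:
        return z[i_hi]
    f = (level - q0) / (q1 - q0)
    return z[i_lo] + f * (z[i_hi] - z[i_lo])


def _edge_width(z, q, idx, level_lo=0.1, level_hi=0.9):
    """10-90% width of one edge; ``idx`` orders samples from outside in."""
    qe = q[idx]
    ze = z[idx]
    above = np.nonzero(qe >= level_hi)[0]
    if above.size == 0:
        raise ValueError("edge never reaches the 90% level")
    i90 = above[0]
    below = np.nonzero(qe[:i90] <= level_lo)[0]
    if below.size == 0:
        raise ValueError("edge never drops to the 10% level")
    i10 = below[-1]
    z10 = _interp_crossing(ze, qe, i10, i10 + 1, level_lo)
    # innermost hi crossing: between i90-1 and i90
    z90 = _interp_crossing(ze, qe, i90 - 1, i90, level_hi) if i90 > 0 else ze[i90]
    return abs(z90 - z10), z10, z90


def penumbral_width(
    volume: VolumeImage,
    background_mu: float | None = None,
) -> PenumbraResult:
    """Measure the 10-90% penumbra of the air cavity on the central axis.

    The profile is inverted and normalized to [0, 1] between the
    background level and the cavity minimum ("pixel-inverse" profile);
    each cavity edge's 10% and 90% crossings are located with sub-voxel
    linear interpolation and the mean of the two edge widths is
    reported.  If ``background_mu`` is not given it is estimated as the
    median of profile samples at least one cavity-diameter away from
    the cavity center.
    """
    z, prof = axial_profile(volume)
    # the cavity must lie inside the object's plateau: samples outside
    # the reconstructed/covered span (e.g. zeros beyond the panel's
    # axial coverage) are not cavity candidates
    bg0 = float(np.percentile(prof, 90.0))
    span = np.nonzero(prof >= 0.8 * bg0)[0]
    if span.size < 2:
        raise ValueError("no cavity found on the central axis")
    lo, hi = int(span[0]), int(span[-1]) + 1
    imin = lo + int(np.argmin(prof[lo:hi]))
    pmin = prof[imin]

    if background_mu is None:
        # first pass: the background is the profile's high plateau (a
        # broad cavity can cover most of the profile, so a plain median
        # would be biased toward the cavity)
        if not pmin < 0.5 * bg0:
            raise ValueError("no cavity found on the central axis")
        # refine: median of samples far from the cavity if any exist,
        # else the plateau samples themselves
        half = 0.5 * (bg0 + pmin)
        inside = np.nonzero(prof <= half)[0]
        halfwidth = max(z[inside[-1]] - z[inside[0]], z[1] - z[0]) / 2.0
        far = np.abs(z - z[imin]) >= 2.0 * halfwidth
        if np.any(far):
            background = float(np.median(prof[far]))
        else:
            background = float(np.median(prof[prof >= 0.9 * bg0]))
    else:
        background = float(background_mu)
    if not pmin < 0.5 * background:
        raise ValueError("no cavity found on the central axis")

    q = (background - prof) / (background - pmin)
    left = np.arange(lo, imin + 1)  # outside-in from -z, within the span
    right = np.arange(hi - 1, imin - 1, -1)  # outside-in from +z
    wl, *_ = _edge_width(z, q, left)
    wr, *_ = _edge_width(z, q, right)
    return PenumbraResult(
        width_mm=float((wl + wr) / 2.0),
        width_left_mm=float(wl),
        width_right_mm=float(wr),
        background=background,
        z=z,
        profile=prof,
        inverse=q,
    )


# ----------------------------------------------------------------------
@dataclass(frozen=True)
class RoiSpec:
    """Circular in-slice region of interest.

    ``center`` is in mm (in-plane); the disc radius is derived from the
    requested ``pixel_count`` via the equal-area relation
    ``r = sqrt(count / pi) * pixel_size`` (e.g. 316 pixels on a 1 mm
    grid -> r = 10.03 mm).
    """

    center: tuple[float, float]
    slice_index: int
    pixel_count: int = 316

    def radius(self, pixel_size: float) -> float:
        return float(np.sqrt(self.pixel_count / np.pi) * pixel_size)


def roi_mask(volume: VolumeImage, roi: RoiSpec) -> np.ndarray:
    """Boolean in-plane mask of the ROI disc on the volume's grid."""
    x = volume.axis_centers(0)
    y = volume.axis_centers(1)
    if abs(volume.voxel_size[0] - volume.voxel_size[1]) > 1e-12:
        raise ValueError("ROI discs require square in-plane pixels")
    r = roi.radius(volume.voxel_size[0])
    d2 = (x[:, None] - roi.center[0]) ** 2 + (y[None, :] - roi.center[1]) ** 2
    return d2 <= r * r


def roi_mean(volume: VolumeImage, roi: RoiSpec) -> float:
    mask = roi_mask(volume, roi)
    return float(volume.values[:, :, roi.slice_index][mask].mean())


def roi_consistency_rmse(series, reference: VolumeImage, roi: RoiSpec) -> float:
    """Normalized RMSE (%) of per-phase ROI means against a reference.

    ``100 * sqrt(mean_t (m_t - m_ref)^2) / m_ref`` where ``m_t`` is the
    ROI mean of phase ``t`` and ``m_ref`` that of the reference image.
    """
    phases = series.phases if hasattr(series, "phases") else list(series)
    m_ref = roi_mean(reference, roi)
    if m_ref == 0:
        raise ValueError("reference ROI mean is zero")
    m = np.array([roi_mean(p, roi) for p in phases])
    return float(100.0 * np.sqrt(np.mean((m - m_ref) ** 2)) / m_ref)


def volume_rmse(a: VolumeImage, b: VolumeImage, mask: np.ndarray | None = None) -> float:
    """Root-mean-square voxel difference, optionally within a mask."""
    d = a.values - b.values
    if mask is not None:
        d = d[mask]
    return float(np.sqrt(np.mean(d**2)))
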