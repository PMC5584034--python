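"""Feldkamp-Davis-Kress filtered backprojection.

Used as the full-scan analytic baseline ("normal 3D" reconstruction) and
as step 1 of the truncated-projection extension procedure.  The
implementation is the standard flat-panel FDK chain: cosine weighting,
row-wise ramp filtering (Ram-Lak kernel, optional Hann apodization,
zero-padded FFT), and distance-weighted voxel-driven backprojection.
Detector coordinates are rescaled to the isocenter plane so the
equispaced fan/cone filtering formulas apply verbatim.
"""

from __future__ import annotations

import numpy as np

from . import _kernels
from .geometry import ScanGeometry
from .projector import ProjectionSet
from .volume import VolumeImage

__all__ = ["reconstruct_fdk", "ramp_kernel"]


def ramp_kernel(n: int, ds: float, window: str = "hann") -> np.ndarray:
    """Frequency response (length ``n`` rfft bins) of the discrete ramp.

    Band-limited Ram-Lak kernel sampled at spacing ``ds`` (Kak-Slaney
    form): ``h(0) = 1/(4 ds^2)``, ``h(k) = -1/(pi k ds)^2`` for odd k,
    0 for even k; optionally apodized by a Hann window over the band.
    """
    k = np.arange(n)
    lag = np.minimum(k, n - k)  # circular: negative lags wrap to the tail
    h = np.zeros(n)
    h[0] = 1.0 / (4.0 * ds**2)
    nz = lag % 2 == 1
    h[nz] = -1.0 / (np.pi * lag[nz] * ds) ** 2
    H = np.real(np.fft.rfft(h))
    if window == "hann":
        f = np.arange(H.size) / (H.size - 1)
        H *= 0.5 * (1.0 + np.cos(np.pi * f))
    elif window not in (None, "ram-lak", "ramlak"):
        raise ValueError(f"unknown filter window {window!r}")
    return H


def _offset_weights(geometry: ScanGeometry) -> np.ndarray | None:
    """Redundancy weights for a laterally offset panel (full-scan use).

    Rays in the doubly covered central band are feathered so that each
    transaxial line integral receives total weight 1 over the 360-degree
    scan; with these weights the usual full-scan factor 1/2 is dropped.
    """
    scale = geometry.sad / geometry.sdd
    u = geometry.u_coords() * scale
    c = geometry.lateral_offset * scale
    half = geometry.detector_cols * geometry.pitch_u / 2.0 * scale
    if c == 0.0:
        return None
    sgn = np.sign(c)
    u0 = half - abs(c)
    if u0 <= 0:  # no redundancy at all
        return np.ones_like(u)
    w = np.ones_like(u)
    band = np.abs(u) <= u0
    w[band] = 0.5 * (1.0 + np.sin(np.pi * sgn * u[band] / (2.0 * u0)))
    w[sgn * u < -u0] = 0.0
    return w


def reconstruct_fdk(
    projections: ProjectionSet,
    geometry: ScanGeometry,
    grid: VolumeImage,
    window: str = "hann",
    clip_negative: bool = True,
    offset_weighting: bool = False,
) -> VolumeImage:
    """FDK reconstruction of line integrals onto the template ``grid``.

    Intended for (near-)full 360-degree angular coverage; the output is
    deterministic and depends on the projections only through the line
    integrals (photon fluence never enters).  Negative values are
    clipped to zero by default so the result can serve directly as an
    attenuation map.
    """
    if projections.n_angles == 0:
        raise ValueError("empty projection set")
    projections.validate_against(geometry)

    scale = geometry.sad / geometry.sdd
    du = geometry.pitch_u * scale
    dv = geometry.pitch_v * scale
    u = geometry.u_coords() * scale
    v = geometry.v_coords() * scale
    cosw = geometry.sad / np.sqrt(geometry.sad**2 + u[None, :] ** 2 + v[:, None] ** 2)

    wred = _offset_weights(geometry) if offset_weighting else None
    full_scan_factor = 0.5 if wred is None else 1.0

    ncols = geometry.detector_cols
    npad = 1 << int(np.ceil(np.log2(max(2 * ncols, 16))))
    H = ramp_kernel(npad, du, window=window)

    if projections.n_angles > 1:
        dbeta = np.deg2rad(abs(np.median(np.diff(projections.angles))))
    else:
        dbeta = np.deg2rad(1.0)

    vol = np.zeros(grid.shape, dtype=np.float64)
    ox, oy, oz = grid.origin
    vx, vy, vz = grid.voxel_size
    weight = full_scan_factor * dbeta
    padded = np.zeros((geometry.detector_rows, npad), dtype=np.float64)
    for frame, ang in zip(projections.frames, projections.angles):
        pw = frame * cosw
        if wred is not None:
            pw = pw * wred[None, :]
        padded[:, :ncols] = pw
        padded[:, ncols:] = 0.0
        filt = np.fft.irfft(np.fft.rfft(padded, axis=1) * H[None, :], axis=1)
        filt = np.ascontiguousarray(filt[:, :ncols]) * du
        th = np.deg2rad(ang)
        _kernels.fdk_backproject_frame(
            vol, ox, oy, oz, vx, vy, vz,
            filt, np.sin(th), np.cos(th), geometry.sad,
            u[0], du, v[0], dv, weight,
        )
    if clip_negative:
        np.maximum(vol, 0.0, out=vol)
    return grid.like(vol)
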