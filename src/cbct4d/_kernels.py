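"""Numba kernels: Siddon ray traversal (forward / adjoint) and voxel-driven
filtered backprojection.

The ray model is a single line from the source to each detector element
center; intersection lengths with the voxel grid are exact (incremental
Siddon traversal).  The backprojection kernel is the exact adjoint of the
forward kernel — it walks the identical voxel/length sequence and
scatter-adds instead of gathering.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_EPS = 1e-12


@njit(cache=True, inline="always")
def _ray_setup(sx, sy, sz, ex, ey, ez, ox, oy, oz, vx, vy, vz, nx, ny, nz):
    """Clip the segment source->element against the grid box.

    Returns (hit, L, tmin, tmax, dirx, diry, dirz)."""
    dirx = ex - sx
    diry = ey - sy
    dirz = ez - sz
    L = np.sqrt(dirx * dirx + diry * diry + dirz * dirz)
    tmin = 0.0
    tmax = 1.0
    # slab clipping, axis by axis
    if dirx != 0.0:
        t1 = (ox - sx) / dirx
        t2 = (ox + nx * vx - sx) / dirx
        if t1 > t2:
            t1, t2 = t2, t1
        if t1 > tmin:
            tmin = t1
        if t2 < tmax:
            tmax = t2
    elif sx < ox or sx >= ox + nx * vx:
        return False, L, 0.0, 0.0, dirx, diry, dirz
    if diry != 0.0:
        t1 = (oy - sy) / diry
        t2 = (oy + ny * vy - sy) / diry
        if t1 > t2:
            t1, t2 = t2, t1
        if t1 > tmin:
            tmin = t1
        if t2 < tmax:
            tmax = t2
    elif sy < oy or sy >= oy + ny * vy:
        return False, L, 0.0, 0.0, dirx, diry, dirz
    if dirz != 0.0:
        t1 = (oz - sz) / dirz
        t2 = (oz + nz * vz - sz) / dirz
        if t1 > t2:
            t1, t2 = t2, t1
        if t1 > tmin:
            tmin = t1
        if t2 < tmax:
            tmax = t2
    elif sz < oz or sz >= oz + nz * vz:
        return False, L, 0.0, 0.0, dirx, diry, dirz
    if tmax - tmin <= _EPS:
        return False, L, 0.0, 0.0, dirx, diry, dirz
    return True, L, tmin, tmax, dirx, diry, dirz


@njit(cache=True, inline="always")
def _axis_init(s0, d, o, v, n, tmin):
    """Entry voxel index and crossing-parameter state for one axis."""
    pos = s0 + tmin * d
    i = int(np.floor((pos - o) / v))
    if i < 0:
        i = 0
    if i > n - 1:
        i = n - 1
    if d > 0.0:
        step = 1
        tnext = ((o + (i + 1) * v) - s0) / d
        dt = v / d
    elif d < 0.0:
        step = -1
        tnext = ((o + i * v) - s0) / d
        dt = -v / d
    else:
        step = 0
        tnext = np.inf
        dt = np.inf
    return i, step, tnext, dt


@njit(cache=True)
def siddon_forward_frame(
    vol, ox, oy, oz, vx, vy, vz,
    sx, sy, sz,
    d0x, d0y, d0z, ux, uy, uz, wx, wy, wz,
    pitch_u, pitch_v, out,
):
    """Line integrals for one frame; ``out`` is (rows, cols)."""
    nx, ny, nz = vol.shape
    nrows, ncols = out.shape
    for r in range(nrows):
        rvx = d0x + r * pitch_v * wx
        rvy = d0y + r * pitch_v * wy
        rvz = d0z + r * pitch_v * wz
        for c in range(ncols):
            ex = rvx + c * pitch_u * ux
            ey = rvy + c * pitch_u * uy
            ez = rvz + c * pitch_u * uz
            hit, L, t, tmax, dx, dy, dz = _ray_setup(
                sx, sy, sz, ex, ey, ez, ox, oy, oz, vx, vy, vz, nx, ny, nz
            )
            acc = 0.0
            if hit:
                ix, sxn, tx, dtx = _axis_init(sx, dx, ox, vx, nx, t)
                iy, syn, ty, dty = _axis_init(sy, dy, oy, vy, ny, t)
                iz, szn, tz, dtz = _axis_init(sz, dz, oz, vz, nz, t)
                while t < tmax - _EPS:
                    tn = tx
                    if ty < tn:
                        tn = ty
                    if tz < tn:
                        tn = tz
                    if tn > tmax:
                        tn = tmax
                    acc += vol[ix, iy, iz] * (tn - t) * L
                    t = tn
                    if tx <= tn + _EPS:
                        ix += sxn
                        tx += dtx
                        if ix < 0 or ix >= nx:
                            break
                    if ty <= tn + _EPS:
                        iy += syn
                        ty += dty
                        if iy < 0 or iy >= ny:
                            break
                    if tz <= tn + _EPS:
                        iz += szn
                        tz += dtz
                        if iz < 0 or iz >= nz:
                            break
            out[r, c] = acc


@njit(cache=True)
def siddon_back_frame(
    vol, ox, oy, oz, vx, vy, vz,
    sx, sy, sz,
    d0x, d0y, d0z, ux, uy, uz, wx, wy, wz,
    pitch_u, pitch_v, frame,
):
    """Adjoint of :func:`siddon_forward_frame`: scatter ``frame`` into ``vol``."""
    nx, ny, nz = vol.shape
    nrows, ncols = frame.shape
    for r in range(nrows):
        rvx = d0x + r * pitch_v * wx
        rvy = d0y + r * pitch_v * wy
        rvz = d0z + r * pitch_v * wz
        for c in range(ncols):
            val = frame[r, c]
            if val == 0.0:
                continue
            ex = rvx + c * pitch_u * ux
            ey = rvy + c * pitch_u * uy
            ez = rvz + c * pitch_u * uz
            hit, L, t, tmax, dx, dy, dz = _ray_setup(
                sx, sy, sz, ex, ey, ez, ox, oy, oz, vx, vy, vz, nx, ny, nz
            )
            if not hit:
                continue
            ix, sxn, tx, dtx = _axis_init(sx, dx, ox, vx, nx, t)
            iy, syn, ty, dty = _axis_init(sy, dy, oy, vy, ny, t)
            iz, szn, tz, dtz = _axis_init(sz, dz, oz, vz, nz, t)
            while t < tmax - _EPS:
                tn = tx
                if ty < tn:
                    tn = ty
                if tz < tn:
                    tn = tz
                if tn > tmax:
                    tn = tmax
                vol[ix, iy, iz] += val * (tn - t) * L
                t = tn
                if tx <= tn + _EPS:
                    ix += sxn
                    tx += dtx
                    if ix < 0 or ix >= nx:
                        break
                if ty <= tn + _EPS:
                    iy += syn
                    ty += dty
                    if iy < 0 or iy >= ny:
                        break
                if tz <= tn + _EPS:
                    iz += szn
                    tz += dtz
                    if iz < 0 or iz >= nz:
                        break


@njit(cache=True)
def fdk_backproject_frame(
    vol, ox, oy, oz, vx, vy, vz,
    filtered, sinb, cosb, sad,
    u0, du, v0, dv, weight,
):
    """Distance-weighted bilinear backprojection of one filtered frame.

    ``filtered`` is sampled on isocenter-rescaled detector coordinates
    ``u0 + j*du`` / ``v0 + i*dv``; contributions falling outside the
    panel are dropped.
    """
    nx, ny, nz = vol.shape
    nrows, ncols = filtered.shape
    for i in range(nx):
        x = ox + (i + 0.5) * vx
        for j in range(ny):
            y = oy + (j + 0.5) * vy
            U = sad - (x * sinb + y * cosb)
            if U < 1e-6:
                continue
            w = weight * sad * sad / (U * U)
            ru = sad * (x * cosb - y * sinb) / U
            fu = (ru - u0) / du
            if fu < 0.0 or fu > ncols - 1:
                continue
            ju = int(fu)
            if ju > ncols - 2:
                ju = ncols - 2
            au = fu - ju
            mag = sad / U
            for k in range(nz):
                z = oz + (k + 0.5) * vz
                fv = (mag * z - v0) / dv
                if fv < 0.0 or fv > nrows - 1:
                    continue
                iv = int(fv)
                if iv > nrows - 2:
                    iv = nrows - 2
                av = fv - iv
                val = (
                    (1 - av) * ((1 - au) * filtered[iv, ju] + au * filtered[iv, ju + 1])
                    + av * ((1 - au) * filtered[iv + 1, ju] + au * filtered[iv + 1, ju + 1])
                )
                vol[i, j, k] += w * val
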