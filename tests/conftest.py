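"""Shared fixtures: small geometries and volumes for fast unit tests."""

from __future__ import annotations

import numpy as np
import pytest

from cbct4d.geometry import make_geometry
from cbct4d.volume import VolumeImage


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_geometry():
    """16 angles on an 8x12 panel; full-scale distances."""
    return make_geometry(n_angles=16, detector_rows=8, detector_cols=12, pitch=20.0)


@pytest.fixture
def small_volume(rng):
    """Random 32-mm-voxel grid centered on the isocenter."""
    return VolumeImage(rng.random((32, 32, 32)) * 0.02, (4.0, 4.0, 4.0), (-64, -64, -64))


def brute_force_ray(values, origin, voxel_size, src, dst):
    """Per-voxel ray/box-intersection oracle (independent of the Siddon
    traversal): sum over every voxel of value x segment length."""
    total = 0.0
    d = dst - src
    L = np.linalg.norm(d)
    nx, ny, nz = values.shape
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                lo = origin + np.array([i, j, k]) * voxel_size
                hi = lo + voxel_size
                tmin, tmax = 0.0, 1.0
                ok = True
                for a in range(3):
                    if d[a] != 0.0:
                        t1 = (lo[a] - src[a]) / d[a]
                        t2 = (hi[a] - src[a]) / d[a]
                        if t1 > t2:
                            t1, t2 = t2, t1
                        tmin = max(tmin, t1)
                        tmax = min(tmax, t2)
                    elif src[a] < lo[a] or src[a] >= hi[a]:
                        ok = False
                        break
                if ok and tmax > tmin:
                    total += values[i, j, k] * (tmax - tmin) * L
    return total
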