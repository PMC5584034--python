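"""Siddon forward projector, its adjoint, and the photon-count model."""

import numpy as np
import pytest

from cbct4d.geometry import make_geometry
from cbct4d.projector import (
    ProjectionSet,
    back_project,
    counts_from_line_integrals,
    forward_project,
)
from cbct4d.volume import VolumeImage

from conftest import brute_force_ray


def _ray_endpoint(geo, angle, row, col):
    org = geo.detector_origin(angle)
    u, v = geo.detector_axes(angle)
    return org + col * geo.pitch_u * u + row * geo.pitch_v * v


class TestForwardProject:
    def test_homogeneous_cube_central_ray(self):
        # 100 mm chord through mu = 0.02 /mm -> line integral 2.0
        vol = VolumeImage(np.full((50, 50, 50), 0.02), (2, 2, 2), (-50, -50, -50))
        geo = make_geometry(n_angles=1, detector_rows=3, detector_cols=3, pitch=5.0)
        p = forward_project(vol, geo)
        assert p.frames[0, 1, 1] == pytest.approx(2.0, rel=1e-9)

    def test_zero_volume_gives_zero_projections(self, small_volume, small_geometry):
        p = forward_project(small_volume.like(np.zeros(small_volume.shape)), small_geometry)
        assert np.all(p.frames == 0.0)

    def test_matches_brute_force_ray_box_oracle(self, rng):
        vol = VolumeImage(rng.random((16, 16, 16)), (3, 3, 3), (-24, -24, -24))
        geo = make_geometry(n_angles=2, detector_rows=2, detector_cols=2, pitch=30.0)
        p = forward_project(vol, geo)
        for ai in range(2):
            src = geo.source_position(geo.angles[ai])
            for r in range(2):
                for c in range(2):
                    ref = brute_force_ray(
                        vol.values,
                        np.array(vol.origin),
                        np.array(vol.voxel_size),
                        src,
                        _ray_endpoint(geo, geo.angles[ai], r, c),
                    )
                    assert p.frames[ai, r, c] == pytest.approx(ref, rel=1e-10)

    def test_chord_length_sums_exactly(self):
        # homogeneous unit volume: line integral equals the chord length
        vol = VolumeImage(np.ones((20, 20, 20)), (5, 5, 5), (-50, -50, -50))
        geo = make_geometry(n_angles=5, detector_rows=4, detector_cols=4, pitch=17.0)
        p = forward_project(vol, geo)
        for ai in range(5):
            src = geo.source_position(geo.angles[ai])
            for r in range(4):
                for c in range(4):
                    ref = brute_force_ray(
                        np.ones((20, 20, 20)),
                        np.array(vol.origin),
                        np.array(vol.voxel_size),
                        src,
                        _ray_endpoint(geo, geo.angles[ai], r, c),
                    )
                    assert p.frames[ai, r, c] == pytest.approx(ref, rel=1e-9, abs=1e-12)

    def test_linearity(self, rng, small_volume, small_geometry):
        x = rng.random(small_volume.shape)
        z = rng.random(small_volume.shape)
        ax = forward_project(small_volume.like(x), small_geometry).frames
        az = forward_project(small_volume.like(z), small_geometry).frames
        combo = forward_project(small_volume.like(2.5 * x - 0.5 * z), small_geometry).frames
        assert np.allclose(combo, 2.5 * ax - 0.5 * az, rtol=1e-12, atol=1e-9)


class TestAdjoint:
    @pytest.mark.parametrize("fov", ["S", "M"])
    def test_adjointness(self, rng, small_volume, fov):
        geo = make_geometry(
            n_angles=16, detector_rows=8, detector_cols=12, pitch=20.0, fov=fov
        )
        x = rng.random(small_volume.shape)
        y = rng.random((16, 8, 12))
        Ax = forward_project(small_volume.like(x), geo).frames
        Aty = back_project(
            ProjectionSet(y, geo.angles, geo.timestamps), geo, small_volume
        ).values
        lhs = float(np.sum(Ax * y))
        rhs = float(np.sum(x * Aty))
        assert lhs == pytest.approx(rhs, rel=1e-6)

    def test_single_element_backprojects_along_one_ray(self, small_volume):
        geo = make_geometry(n_angles=4, detector_rows=3, detector_cols=3, pitch=30.0)
        y = np.zeros((4, 3, 3))
        y[1, 1, 1] = 1.0
        vol = back_project(ProjectionSet(y, geo.angles, geo.timestamps), geo, small_volume)
        # values along the ray are the per-voxel path lengths
        src = geo.source_position(geo.angles[1])
        dst = _ray_endpoint(geo, geo.angles[1], 1, 1)
        for idx in zip(*np.nonzero(vol.values)):
            e = np.zeros(small_volume.shape)
            e[idx] = 1.0
            ref = brute_force_ray(
                e, np.array(small_volume.origin), np.array(small_volume.voxel_size), src, dst
            )
            assert vol.values[idx] == pytest.approx(ref, rel=1e-10)
        assert np.count_nonzero(vol.values) > 0

    def test_zero_projections_give_zero_volume(self, small_volume, small_geometry):
        y = np.zeros((16, 8, 12))
        geo = small_geometry
        vol = back_project(ProjectionSet(y, geo.angles, geo.timestamps), geo, small_volume)
        assert np.all(vol.values == 0.0)

    def test_shape_mismatch_rejected(self, small_volume, small_geometry):
        y = np.zeros((16, 4, 4))
        pset = ProjectionSet(y, small_geometry.angles, small_geometry.timestamps)
        with pytest.raises(ValueError):
            back_project(pset, small_geometry, small_volume)


class TestCounts:
    def test_zero_line_integral_gives_n0(self, small_geometry):
        y = np.zeros((16, 8, 12))
        p = ProjectionSet(y, small_geometry.angles, small_geometry.timestamps, n0=1234.0)
        assert np.all(counts_from_line_integrals(p) == 1234.0)

    def test_ln2_halves_counts(self, small_geometry):
        y = np.full((16, 8, 12), np.log(2.0))
        p = ProjectionSet(y, small_geometry.angles, small_geometry.timestamps)
        n = counts_from_line_integrals(p, n0=1000.0)
        assert np.allclose(n, 500.0)

    def test_poisson_sampling_mean(self, small_geometry):
        y = np.ones((16, 25, 25))
        p = ProjectionSet(y, small_geometry.angles, small_geometry.timestamps)
        n = counts_from_line_integrals(p, n0=1e5, noisy=True, seed=7)
        mean = 1e5 * np.exp(-1.0)
        sem = np.sqrt(mean / n.size)
        assert abs(n.mean() - mean) < 3 * sem
        # reproducible for a fixed seed
        n2 = counts_from_line_integrals(p, n0=1e5, noisy=True, seed=7)
        assert np.array_equal(n, n2)

    def test_negative_line_integrals_rejected(self, small_geometry):
        y = np.full((16, 8, 12), -0.1)
        p = ProjectionSet(y, small_geometry.angles, small_geometry.timestamps)
        with pytest.raises(ValueError):
            counts_from_line_integrals(p)
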