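"""Objective terms: smoothed TV, prior-image and time-chain terms, and the
Poisson transmission log-likelihood."""

import numpy as np
import pytest

from cbct4d.geometry import make_geometry
from cbct4d.objectives import (
    PoissonDataTerm,
    neg_log_likelihood,
    pic_term,
    tcgm_term,
    tv_norm,
)
from cbct4d.projector import ProjectionSet, forward_project
from cbct4d.volume import VolumeImage

EPS = 1e-8


def brute_force_tv(m, eps):
    nx, ny, nz = m.shape
    total = 0.0
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                dx = m[i, j, k] - m[i + 1, j, k] if i + 1 < nx else 0.0
                dy = m[i, j, k] - m[i, j + 1, k] if j + 1 < ny else 0.0
                dz = m[i, j, k] - m[i, j, k + 1] if k + 1 < nz else 0.0
                total += np.sqrt(dx * dx + dy * dy + dz * dz + eps)
    return total


class TestTvNorm:
    def test_constant_volume(self):
        m = np.full((3, 4, 5), 0.7)
        assert tv_norm(m, EPS) == pytest.approx(60 * np.sqrt(EPS))

    def test_two_voxel_step(self):
        m = np.array([1.0, 0.0]).reshape(2, 1, 1)
        assert tv_norm(m, 0.0) == pytest.approx(1.0)

    def test_matches_brute_force_summation(self, rng):
        m = rng.random((6, 6, 6))
        assert tv_norm(m, EPS) == pytest.approx(brute_force_tv(m, EPS), abs=1e-12)

    def test_gradient_matches_finite_differences(self, rng):
        m = rng.random((5, 5, 5))
        _, g = tv_norm(m, 1e-6, with_grad=True)
        h = 1e-7
        for idx in [(0, 0, 0), (2, 3, 1), (4, 4, 4), (1, 0, 3)]:
            m1, m2 = m.copy(), m.copy()
            m1[idx] += h
            m2[idx] -= h
            fd = (tv_norm(m1, 1e-6) - tv_norm(m2, 1e-6)) / (2 * h)
            assert g[idx] == pytest.approx(fd, rel=1e-5, abs=1e-9)


class TestPicTerm:
    def test_minimum_at_prior(self, rng):
        p = rng.random((4, 4, 4))
        assert pic_term(p, p, EPS) == pytest.approx(64 * np.sqrt(EPS))

    def test_zero_prior_reduces_to_tv(self, rng):
        m = rng.random((4, 4, 4))
        assert pic_term(m, np.zeros_like(m), EPS) == pytest.approx(tv_norm(m, EPS))

    def test_equals_tv_of_difference(self, rng):
        m, p = rng.random((5, 4, 3)), rng.random((5, 4, 3))
        assert pic_term(m, p, EPS) == pytest.approx(tv_norm(m - p, EPS))

    def test_grid_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            pic_term(rng.random((4, 4, 4)), rng.random((5, 4, 4)), EPS)


class TestTcgmTerm:
    def test_interior_minimum_is_doubled_constant(self):
        m = np.full((4, 4, 4), 0.3)
        series = [m, m, m]
        assert tcgm_term(series, 1, EPS) == pytest.approx(2 * 64 * np.sqrt(EPS))

    def test_boundary_phase_doubles_one_sided_term(self):
        m = np.full((4, 4, 4), 0.3)
        series = [m, m]
        # equal phases: boundary value equals the interior minimum
        assert tcgm_term(series, 0, EPS) == pytest.approx(2 * 64 * np.sqrt(EPS))
        # unequal phases: exactly twice the single one-sided TV
        other = m + np.linspace(0, 1, 64).reshape(4, 4, 4)
        assert tcgm_term([m, other], 0, EPS) == pytest.approx(
            2 * tv_norm(m - other, EPS)
        )
        assert tcgm_term([m, other], 1, EPS) == pytest.approx(
            2 * tv_norm(other - m, EPS)
        )

    def test_interior_is_sum_of_neighbor_tvs(self, rng):
        a, b, c = (rng.random((4, 4, 4)) for _ in range(3))
        expected = tv_norm(b - a, EPS) + tv_norm(b - c, EPS)
        assert tcgm_term([a, b, c], 1, EPS) == pytest.approx(expected)

    def test_single_phase_rejected(self, rng):
        with pytest.raises(ValueError):
            tcgm_term([rng.random((3, 3, 3))], 0, EPS)


class TestPoissonData:
    def _toy(self, rng, shape=(8, 8, 8)):
        geo = make_geometry(n_angles=4, detector_rows=4, detector_cols=4, pitch=8.0)
        grid = VolumeImage(rng.random(shape) * 0.02, (4, 4, 4), (-16, -16, -16))
        y = forward_project(grid, geo)
        meas = ProjectionSet(
            y.frames + 0.1 * rng.random(y.frames.shape),
            geo.angles,
            geo.timestamps,
            n0=1e4,
        )
        return geo, grid, meas

    def test_gradient_matches_finite_differences(self, rng):
        geo, grid, meas = self._toy(rng)
        data = PoissonDataTerm(meas, geo, grid)
        mu = rng.random((8, 8, 8)) * 0.02
        g = data.gradient(data.forward(mu))
        h = 1e-6
        for idx in [(0, 0, 0), (4, 4, 4), (7, 2, 5), (3, 6, 1)]:
            m1, m2 = mu.copy(), mu.copy()
            m1[idx] += h
            m2[idx] -= h
            fd = (data.value(data.forward(m1)) - data.value(data.forward(m2))) / (2 * h)
            assert g[idx] == pytest.approx(fd, rel=1e-5, abs=1e-8)

    def test_stationary_at_noiseless_truth(self, rng):
        geo = make_geometry(n_angles=6, detector_rows=4, detector_cols=4, pitch=8.0)
        grid = VolumeImage(rng.random((8, 8, 8)) * 0.02, (4, 4, 4), (-16, -16, -16))
        meas = forward_project(grid, geo)
        data = PoissonDataTerm(meas, geo, grid)
        # directional finite difference along a random direction ~ 0
        d = rng.standard_normal((8, 8, 8))
        d /= np.linalg.norm(d)
        h = 1e-5
        f = lambda m: data.value(data.forward(m))
        fd = (f(grid.values + h * d) - f(grid.values - h * d)) / (2 * h)
        scale = np.linalg.norm(data.gradient(data.forward(np.zeros((8, 8, 8)))))
        assert abs(fd) / scale < 1e-4

    def test_single_element_closed_form(self):
        # one voxel, one ray of unit path length: value = n y + n0 e^{-y}
        geo = make_geometry(n_angles=1, detector_rows=1, detector_cols=1, pitch=1.0)
        grid = VolumeImage(np.full((1, 1, 1), 0.3), (1, 1, 1), (-0.5, -0.5, -0.5))
        meas = ProjectionSet(
            np.full((1, 1, 1), np.log(2.0)), geo.angles, geo.timestamps, n0=100.0
        )
        val = neg_log_likelihood(grid, meas, geo)
        assert val == pytest.approx(50.0 * 0.3 + 100.0 * np.exp(-0.3))

    def test_curvature_diag_positive_inside_fov(self, rng):
        geo, grid, meas = self._toy(rng)
        data = PoissonDataTerm(meas, geo, grid)
        D = data.curvature_diag()
        assert np.all(D >= 0)
        assert D[4, 4, 4] > 0
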