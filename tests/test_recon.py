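"""MAP solver: toy convergence, monotonicity, symmetry, constraints."""

import numpy as np
import pytest

from cbct4d.binning import assign_phases
from cbct4d.fdk import reconstruct_fdk
from cbct4d.geometry import make_geometry
from cbct4d.metrics import volume_rmse
from cbct4d.phantom import phantom_preset, phantom_volume
from cbct4d.projector import ProjectionSet
from cbct4d.recon import ReconConfig, TimeSeriesImage, reconstruct_iterative
from cbct4d.simulate import simulate_scan
from cbct4d.volume import VolumeImage


def _single_ray_problem():
    geo = make_geometry(n_angles=1, detector_rows=1, detector_cols=1, pitch=1.0)
    vol = VolumeImage(np.zeros((1, 1, 1)), (1.0, 1.0, 1.0), (-0.5, -0.5, -0.5))
    meas = ProjectionSet(
        np.full((1, 1, 1), np.log(2.0)), geo.angles, geo.timestamps, n0=100.0
    )
    return geo, vol, meas


class TestToyProblems:
    def test_single_voxel_mle_is_ln2(self):
        # n0 = 100, n = 50 on a unit path: the pure likelihood maximizer
        # of the transmission model is mu = ln 2
        geo, vol, meas = _single_ray_problem()
        cfg = ReconConfig(
            alpha=0, beta=0, gamma=0, lambda_reg=0.0, n_iterations=100, n0=100.0
        )
        rr = reconstruct_iterative(meas, None, geo, cfg, vol)
        assert rr.series[0].values[0, 0, 0] == pytest.approx(np.log(2.0), abs=1e-6)
        assert not rr.diverged

    def test_objective_history_non_increasing(self):
        geo, vol, meas = _single_ray_problem()
        cfg = ReconConfig(alpha=1.0, lambda_reg=10.0, n_iterations=50, n0=100.0)
        rr = reconstruct_iterative(meas, None, geo, cfg, vol)
        assert np.all(np.diff(rr.objective) <= 1e-9 * np.abs(rr.objective[:-1]))

    def test_beta_without_prior_rejected(self):
        geo, vol, meas = _single_ray_problem()
        cfg = ReconConfig(alpha=0.1, beta=0.9, n_iterations=2)
        with pytest.raises(ValueError):
            reconstruct_iterative(meas, None, geo, cfg, vol)


@pytest.fixture(scope="module")
def tiny_scan():
    """Fast static-phantom scan for solver behavior tests."""
    spec = phantom_preset(
        "static", grid_dims=(32, 32, 24), voxel_size=(8.0, 8.0, 3.5)
    )
    geo = make_geometry(
        n_angles=60, detector_rows=28, detector_cols=48, pitch_v=4.8, pitch_u=8.5334
    )
    proj = simulate_scan(spec, geo)
    return spec, geo, proj


class TestSolverBehavior:
    def test_tvcs_beats_fdk_on_static_phantom(self, tiny_scan):
        spec, geo, proj = tiny_scan
        fdk_vol = reconstruct_fdk(proj, geo, spec.grid())
        cfg = ReconConfig.preset("tvcs", n_iterations=30, lambda_balance=0.01)
        rr = reconstruct_iterative(proj, None, geo, cfg, fdk_vol)
        gt = phantom_volume(spec, 0.0)
        assert volume_rmse(rr.series[0], gt) < volume_rmse(fdk_vol, gt)
        assert np.all(np.diff(rr.objective) <= 1e-9 * np.abs(rr.objective[:-1]))

    def test_outputs_nonnegative(self, tiny_scan):
        spec, geo, proj = tiny_scan
        fdk_vol = reconstruct_fdk(proj, geo, spec.grid())
        binning = assign_phases(proj, 3, 200.0)
        cfg = ReconConfig.preset("tcgm", n_iterations=5, lambda_balance=0.01)
        rr = reconstruct_iterative(proj, binning, geo, cfg, fdk_vol)
        for phase in rr.series.phases:
            assert np.all(phase.values >= 0.0)

    def test_two_identical_phases_agree(self, tiny_scan):
        # same data in both windows + symmetric coupling: the two phase
        # images must coincide (up to solver asymmetry of the sweep)
        spec, geo, proj = tiny_scan
        fdk_vol = reconstruct_fdk(proj, geo, spec.grid())
        binning = assign_phases(proj, 2, 2 * geo.angular_range)
        assert binning.windows[0] == binning.windows[1]
        cfg = ReconConfig.preset("tcgm", n_iterations=80, lambda_balance=0.01)
        rr = reconstruct_iterative(proj, binning, geo, cfg, fdk_vol)
        a, b = rr.series[0].values, rr.series[1].values
        assert np.max(np.abs(a - b)) < 1e-3 * spec.body_mu

    def test_deterministic_for_fixed_config(self, tiny_scan):
        spec, geo, proj = tiny_scan
        fdk_vol = reconstruct_fdk(proj, geo, spec.grid())
        cfg = ReconConfig.preset("tvcs", n_iterations=5, lambda_balance=0.01)
        a = reconstruct_iterative(proj, None, geo, cfg, fdk_vol)
        b = reconstruct_iterative(proj, None, geo, cfg, fdk_vol)
        assert np.array_equal(a.series[0].values, b.series[0].values)
        assert np.array_equal(a.objective, b.objective)

    def test_series_initial_and_per_phase_prior(self, tiny_scan):
        spec, geo, proj = tiny_scan
        fdk_vol = reconstruct_fdk(proj, geo, spec.grid())
        binning = assign_phases(proj, 3, 200.0)
        series = TimeSeriesImage.constant(fdk_vol, 3)
        cfg = ReconConfig.preset("piccs", n_iterations=3, lambda_balance=0.01)
        rr = reconstruct_iterative(proj, binning, geo, cfg, series, prior=series)
        assert len(rr.series) == 3

    def test_gamma_requires_multiple_phases(self, tiny_scan):
        spec, geo, proj = tiny_scan
        fdk_vol = reconstruct_fdk(proj, geo, spec.grid())
        cfg = ReconConfig.preset("tcgm", n_iterations=2)
        with pytest.raises(ValueError):
            reconstruct_iterative(proj, None, geo, cfg, fdk_vol)
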