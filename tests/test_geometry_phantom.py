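"""Scan geometry construction and the moving-sphere phantom."""

import numpy as np
import pytest

from cbct4d.geometry import GeometryError, make_geometry
from cbct4d.phantom import (
    PhantomError,
    PhantomSpec,
    occupancy_edge_oracle,
    phantom_preset,
    phantom_volume,
    sphere_center,
)


class TestMakeGeometry:
    def test_default_schedule_360_degrees_in_60_seconds(self):
        geo = make_geometry()
        assert geo.n_angles == 360
        assert np.allclose(np.diff(geo.angles), 1.0)
        # 6 deg/s rotation: one frame every 1/6 s
        assert np.allclose(np.diff(geo.timestamps), 1.0 / 6.0)
        assert geo.lateral_offset == 0.0  # S FOV

    def test_medium_fov_preset_offsets_panel(self):
        geo = make_geometry(fov="M")
        assert geo.lateral_offset == 115.0
        assert make_geometry(fov="L").lateral_offset == 190.0

    def test_degenerate_distances_rejected(self):
        with pytest.raises(GeometryError):
            make_geometry(sad=1000.0, sdd=1000.0)

    def test_non_monotonic_timestamps_rejected(self):
        with pytest.raises(GeometryError):
            make_geometry(
                n_angles=3, angles=[0.0, 1.0, 2.0], timestamps=[0.0, 2.0, 1.0]
            )

    def test_long_config_names_accepted(self):
        geo = make_geometry(
            {"source_to_axis_distance": 900.0, "source_to_detector_distance": 1400.0}
        )
        assert geo.sad == 900.0 and geo.sdd == 1400.0


class TestPhantom:
    def test_sphere_center_clamps_and_interpolates(self):
        spec = phantom_preset("3cm60s")
        assert sphere_center(spec, 0.0) == -15.0
        assert sphere_center(spec, 60.0) == 15.0
        assert sphere_center(spec, 30.0) == 0.0
        assert sphere_center(spec, -5.0) == -15.0  # clamped before start

    def test_fast_motion_waits_for_quarter_rotation(self):
        # 3 cm / 30 s: motion only while the source sweeps 90 -> 270 deg
        spec = phantom_preset("3cm30s")
        assert sphere_center(spec, 10.0) == -15.0  # source at 60 deg, still parked
        assert sphere_center(spec, 15.0) == -15.0
        assert sphere_center(spec, 30.0) == 0.0
        assert sphere_center(spec, 50.0) == 15.0

    def test_sphere_volume_matches_analytic(self):
        spec = phantom_preset(
            "3cm60s", grid_dims=(48, 48, 48), voxel_size=(1.0, 1.0, 1.0)
        )
        vol = phantom_volume(spec, 30.0)
        count = np.sum(vol.values == spec.sphere_mu)
        analytic = 4.0 / 3.0 * np.pi * spec.sphere_radius**3
        shell = 4.0 * np.pi * spec.sphere_radius**2 * 1.0  # one voxel-shell
        assert abs(count - analytic) < shell

    def test_translation_consistency(self):
        spec = phantom_preset(
            "3cm60s", grid_dims=(48, 48, 60), voxel_size=(1.0, 1.0, 1.0)
        )
        # 0.5 mm/s: 8 s apart -> exactly 4 voxels of axial shift
        a = phantom_volume(spec, 20.0).values
        b = phantom_volume(spec, 28.0).values
        pa = (a == spec.sphere_mu).sum(axis=(0, 1)).astype(float)
        pb = (b == spec.sphere_mu).sum(axis=(0, 1)).astype(float)
        xc = np.correlate(pb, pa, mode="full")
        shift = int(np.argmax(xc)) - (len(pa) - 1)
        assert shift == 4

    def test_sphere_outside_cylinder_rejected(self):
        with pytest.raises(PhantomError):
            PhantomSpec(ellipse_semi_axis_y=10.0)  # 15 mm sphere cannot fit


class TestOccupancyOracle:
    @pytest.mark.parametrize(
        "extent,expected",
        [(30.0, 24.0), (15.0, 12.0), (1e-9, 0.8e-9)],
    )
    def test_closed_form_width(self, extent, expected):
        spec = phantom_preset("3cm60s", motion_extent=extent)
        _, _, width = occupancy_edge_oracle(spec)
        assert width == pytest.approx(expected)

    def test_width_linear_in_extent_below_diameter(self):
        widths = []
        for L in (6.0, 12.0, 24.0):
            spec = phantom_preset("3cm60s", motion_extent=L)
            widths.append(occupancy_edge_oracle(spec)[2])
        assert np.allclose(widths, [0.8 * L for L in (6.0, 12.0, 24.0)])

    def test_profile_is_unit_plateau_trapezoid(self):
        spec = phantom_preset("3cm60s")
        z, occ, _ = occupancy_edge_oracle(spec)
        assert occ.max() == pytest.approx(1.0)
        assert occ.min() == 0.0
        # plateau where the whole motion interval lies inside the sphere
        inside = np.abs(z) < spec.sphere_radius - spec.motion_extent / 2.0
        assert np.all(occ[inside] == 1.0)
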