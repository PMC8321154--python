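"""Geometry mappings and derived optical quantities."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from xlfemu import presets
from xlfemu.geometry import (
    CrystalDesign,
    GeometryError,
    LensDesign,
    OpticalAxisFrame,
    PolycapDesign,
    angular_range,
    beamlet_waist,
    camera_resolutions,
    critical_angle,
    emulate_crystal,
    emulate_lens,
    emulate_polycap,
    emulation_pixel_size,
    grid_emulation_geometry,
    load_design,
    save_design,
    separation_ok,
    spatial_magnification,
)


class TestFrames:
    def test_rejects_degenerate_axial_order(self):
        with pytest.raises(GeometryError):
            OpticalAxisFrame(z0=500.0, zsd=500.0)
        with pytest.raises(GeometryError):
            OpticalAxisFrame(z0=-1.0, zsd=10.0)

    def test_cone_magnification(self):
        f = OpticalAxisFrame(z0=100.0, zsd=150.0)
        assert f.cone_magnification == pytest.approx(1.5)


class TestCrystalMapping:
    def test_hand_evaluated_source_position(self):
        design = CrystalDesign(
            phi_centers=((0.0, 0.0), (10.0, 0.0)),
            frame=OpticalAxisFrame(z0=500.0, zsd=550.0),
        )
        geom = emulate_crystal(design)
        off_axis = [v for v in geom.views if v.detector != (0.0, 0.0)][0]
        assert off_axis.source == pytest.approx((-100.0, 0.0))
        assert off_axis.detector == pytest.approx((10.0, 0.0))

    def test_central_beam_fixed_point(self):
        design = CrystalDesign(
            phi_centers=((0.0, 0.0), (5.0, -3.0)),
            frame=OpticalAxisFrame(z0=500.0, zsd=550.0),
        )
        geom = emulate_crystal(design)
        central = geom.views[geom.central_index]
        assert central.source == (0.0, 0.0)
        assert central.detector == (0.0, 0.0)

    def test_lines_cross_axis_at_focal_plane(self):
        design = CrystalDesign(
            phi_centers=((0.0, 0.0), (10.0, 0.0), (-4.0, 7.0)),
            frame=OpticalAxisFrame(z0=500.0, zsd=550.0),
        )
        geom = emulate_crystal(design)
        assert geom.collinearity_residuals().max() < 1e-9

    def test_requires_transmitted_beam(self):
        with pytest.raises(GeometryError):
            CrystalDesign(
                phi_centers=((10.0, 0.0),),
                frame=OpticalAxisFrame(z0=500.0, zsd=550.0),
            )

    def test_cone_distortion_warning(self):
        design = CrystalDesign(
            phi_centers=((0.0, 0.0), (10.0, 0.0)),
            frame=OpticalAxisFrame(z0=500.0, zsd=800.0),
        )
        with pytest.warns(UserWarning, match="distortion"):
            emulate_crystal(design)


class TestPolycapMapping:
    def make_design(self, **kw):
        params = dict(
            hole_pitch_u=2.0, hole_pitch_v=2.0, n_views_u=3, n_views_v=3,
            a_in=10.0, a_out=5.0, energy=9.0,
            frame=OpticalAxisFrame(z0=100.0, zsd=150.0),
        )
        params.update(kw)
        return PolycapDesign(**params)

    def test_taper_factor(self):
        assert self.make_design().taper_factor == pytest.approx(0.5)

    def test_hand_evaluated_positions(self):
        geom = emulate_polycap(self.make_design())
        view = next(v for v in geom.views if v.index == (1, 0))
        # H = (2, 0) mm demagnified by t = 0.5
        assert view.source == pytest.approx((1.0, 0.0))
        assert view.detector == pytest.approx((-0.5, 0.0))

    def test_central_hole_fixed_point(self):
        geom = emulate_polycap(self.make_design())
        central = geom.views[geom.central_index]
        assert central.source == (0.0, 0.0) and central.detector == (0.0, 0.0)

    def test_even_grid_rejected(self):
        with pytest.raises(GeometryError):
            self.make_design(n_views_u=4)


class TestLensMapping:
    def test_reference_grid_positions(self):
        geom = presets.reference_geometry()
        assert geom.n_views == 81
        assert geom.u_max == pytest.approx(8.0)
        view = next(v for v in geom.views if v.index == (1, 0))
        assert view.source == pytest.approx((2.0, 0.0))
        assert view.detector[0] == pytest.approx(-0.27444, abs=1e-4)

    def test_view_ordering_row_major_pv_outer(self):
        geom = presets.reference_geometry(n_views=3)
        indices = [tuple(v.index) for v in geom.views]
        assert indices == [
            (-1, -1), (0, -1), (1, -1),
            (-1, 0), (0, 0), (1, 0),
            (-1, 1), (0, 1), (1, 1),
        ]

    def test_angular_range_matches_camera_when_spacing_scaled(self):
        design = presets.reference_lens_design()
        frame = presets.reference_frame()
        geom = emulate_lens(design, frame)  # matched spacing
        _, _, du, _ = camera_resolutions(design)
        cam_range = angular_range(4 * du * 1e-3, design.z0_cam)
        assert abs(geom.angular_range() - cam_range) < 1e-6

    def test_unfocused_configuration_enforced(self):
        with pytest.raises(GeometryError, match="z2 = f2"):
            LensDesign(
                f1=41.0, f2=9.0, z0_cam=49.48, z1=243.71, z2=8.78,
                ml_diameter=1000, mla_lens_diameter=32, mla_pitch=36,
                sensor_pixel=4, n_views_u=9, n_views_v=9,
            )


class TestResolutions:
    def test_camera_spatial_resolution(self):
        design = presets.reference_lens_design()
        ds, dt, du, dv = camera_resolutions(design)
        assert ds == pytest.approx(36.0 / (243.71 / 49.48), rel=1e-6)
        assert ds == pytest.approx(7.309, abs=1e-3)
        assert du == pytest.approx(4.0 / (8.78 / 243.71), rel=1e-6)
        assert du == pytest.approx(111.0, abs=0.1)

    def test_unit_magnification_returns_pitch(self):
        design = LensDesign(
            f1=25.0, f2=10.0, z0_cam=50.0, z1=50.0, z2=10.0,
            ml_diameter=1000, mla_lens_diameter=32, mla_pitch=36,
            sensor_pixel=4, n_views_u=3, n_views_v=3,
        )
        ds, *_ = camera_resolutions(design)
        assert ds == pytest.approx(36.0)

    def test_emulation_pixel_size(self):
        frame = presets.reference_frame()
        assert emulation_pixel_size(150.0, frame) == pytest.approx(131.9, abs=0.05)
        half = OpticalAxisFrame(z0=100.0, zsd=200.0)
        assert emulation_pixel_size(150.0, half) == pytest.approx(75.0)

    def test_spatial_magnification_rounds_to_18(self):
        assert round(spatial_magnification(131.55, 7.309)) == 18
        assert round(spatial_magnification(131.9, 7.309)) == 18
        assert spatial_magnification(5.0, 5.0) == pytest.approx(1.0)


class TestAngularRange:
    def test_reference_value(self):
        assert round(angular_range(8.0, 890.725), 3) == 1.029

    def test_zero_aperture(self):
        assert angular_range(0.0, 100.0) == 0.0

    def test_camera_side_agrees_with_emulation(self):
        cam = angular_range(4 * 111.03e-3, 49.48)
        assert cam == pytest.approx(1.029, abs=2e-3)

    @given(
        u=st.floats(0.1, 50.0), z=st.floats(10.0, 2000.0),
        du=st.floats(0.01, 10.0), dz=st.floats(0.01, 500.0),
    )
    @settings(derandomize=True, max_examples=50)
    def test_monotone_in_aperture_and_distance(self, u, z, du, dz):
        assert angular_range(u + du, z) > angular_range(u, z)
        assert angular_range(u, z + dz) < angular_range(u, z)


class TestPolycapFeasibility:
    def test_critical_angle(self):
        assert critical_angle(30.0) == pytest.approx(1.0)
        assert critical_angle(9.0) == pytest.approx(3.333, abs=1e-3)

    def test_beamlet_waist(self):
        # z0 = 10 mm at phi = 1 mrad -> 20 um
        assert beamlet_waist(10.0, 30.0) == pytest.approx(20.0)

    def test_separation_inequality(self):
        w = beamlet_waist(10.0, 30.0)
        assert separation_ok(25.0, w)
        assert not separation_ok(15.0, w)


@given(
    z0=st.floats(50.0, 1000.0),
    extra=st.floats(1.0, 500.0),
    spacing=st.floats(0.1, 10.0),
    n=st.sampled_from([3, 5, 9]),
)
@settings(derandomize=True, max_examples=60)
def test_collinearity_invariant_randomized(z0, extra, spacing, n):
    """Every emitted S→D line crosses the axis at z0 (to 1e-9 mm)."""
    frame = OpticalAxisFrame(z0=z0, zsd=z0 + extra)
    geom = grid_emulation_geometry(frame, n, n, spacing)
    assert geom.collinearity_residuals().max() < 1e-9


@given(z0=st.floats(50.0, 1000.0), extra=st.floats(1.0, 500.0),
       spacing=st.floats(0.1, 10.0))
@settings(derandomize=True, max_examples=40)
def test_source_detector_sign_opposition(z0, extra, spacing):
    """D and S sit on opposite sides of the axis componentwise (zsd > z0)."""
    frame = OpticalAxisFrame(z0=z0, zsd=z0 + extra)
    geom = grid_emulation_geometry(frame, 3, 3, spacing)
    s = geom.source_positions
    d = geom.detector_positions
    assert np.all(s * d <= 1e-12)


class TestDesignIO:
    def test_json_roundtrip_all_types(self, tmp_path):
        designs = [
            presets.reference_lens_design(),
            PolycapDesign(
                hole_pitch_u=2.0, hole_pitch_v=2.0, n_views_u=3, n_views_v=3,
                a_in=10.0, a_out=5.0, energy=9.0,
                frame=OpticalAxisFrame(z0=100.0, zsd=150.0),
            ),
            CrystalDesign(
                phi_centers=((0.0, 0.0), (10.0, 0.0)),
                frame=OpticalAxisFrame(z0=500.0, zsd=550.0),
            ),
        ]
        for i, design in enumerate(designs):
            path = tmp_path / f"design_{i}.json"
            save_design(design, path)
            assert load_design(path) == design

    def test_scan_plan_csv(self, tmp_path):
        import pandas as pd

        geom = presets.reference_geometry(n_views=3)
        path = tmp_path / "plan.csv"
        geom.to_csv(path)
        table = pd.read_csv(path)
        assert len(table) == 9
        assert list(table.columns) == [
            "pu", "pv", "S_u_mm", "S_v_mm", "D_x_mm", "D_y_mm"
        ]
        central = table[(table.pu == 0) & (table.pv == 0)].iloc[0]
        assert central.S_u_mm == 0.0 and central.D_x_mm == 0.0
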