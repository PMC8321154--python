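"""Depth cues and the regularized two-cue merge."""

import dataclasses

import numpy as np
import pytest
from scipy.ndimage import map_coordinates

from xlfemu import presets
from xlfemu.depthmap import (
    CueResponse,
    correspondence_cue,
    defocus_cue,
    estimate_depthmap,
    merge_cues,
)
from xlfemu.lightfield import LightField
from xlfemu.preprocess import preprocess_branch
from xlfemu.refocus import FocalStack, default_z_samples, focal_stack

Z0, ZSD = presets.Z0, presets.ZSD
BEAD_Z = Z0 + 10.0


def textured_plane_lightfield(geometry, z_star, seed=0):
    """Analytic light-field of a band-limited random texture on the plane z*.

    Each view sees the texture sampled at the object point its pixel ray
    crosses at depth z*: an exact, projector-free oracle for cue recovery.
    The texture is low-pass filtered below the pixel Nyquist so that
    interpolation attenuation in the refocuser stays negligible against the
    alignment signal.
    """
    from scipy.ndimage import gaussian_filter

    rng = np.random.default_rng(seed)
    nx, ny = geometry.detector_pixels
    pitch_fp = geometry.effective_pixel * 1e-3
    # texture on a grid 3× the field of view so every view stays inside
    t_n = 3 * max(nx, ny)
    texture = gaussian_filter(rng.normal(size=(t_n, t_n)), 1.5)
    pitch_det = geometry.detector_pitch * 1e-3
    images = np.empty((geometry.n_views, ny, nx))
    for i, view in enumerate(geometry.views):
        su, sv = view.source
        dx, dy = view.detector
        xs = dx + (np.arange(nx) - (nx - 1) / 2) * pitch_det
        ys = dy + (np.arange(ny) - (ny - 1) / 2) * pitch_det
        # object point at depth z*: p = S + (x_det - S)·z*/zsd
        px = su + (xs - su) * z_star / ZSD
        py = sv + (ys - sv) * z_star / ZSD
        col = px / pitch_fp + (t_n - 1) / 2
        row = py / pitch_fp + (t_n - 1) / 2
        rows, cols = np.meshgrid(row, col, indexing="ij")
        images[i] = map_coordinates(texture, [rows, cols], order=1,
                                    mode="constant", cval=0.0)
    return LightField(images=images, geometry=geometry)


class TestDefocusCue:
    def test_constant_stack_zero_confidence(self):
        stack = FocalStack(images=np.full((5, 32, 32), 2.0),
                           z_samples=np.arange(5.0), pixel_pitch=0.1)
        cue = defocus_cue(stack, z_ref=2.0)
        assert np.allclose(cue.confidence, 0.0)

    def test_needs_three_planes(self):
        stack = FocalStack(images=np.zeros((2, 8, 8)),
                           z_samples=np.array([0.0, 1.0]), pixel_pitch=0.1)
        with pytest.raises(ValueError):
            defocus_cue(stack)

    def test_textured_plane_recovered(self, small_geometry):
        # the plane must sit at least ~one DoF off-focus: inside the DoF the
        # sharpness curve is flat by construction and carries no depth signal
        z_star = Z0 - 16.0
        lf = textured_plane_lightfield(small_geometry, z_star)
        zs = default_z_samples(small_geometry)
        cue = defocus_cue(focal_stack(lf, zs), z_ref=Z0)
        step = zs[1] - zs[0]
        interior = cue.best_depth[16:-16, 16:-16]
        median_depth = np.median(interior)
        assert abs(median_depth - z_star) <= step + 1e-9

    def test_two_lateral_regions_recovered(self, small_geometry):
        """Two textured half-planes at different depths are each assigned
        their own depth."""
        za, zb = Z0 - 15.0, Z0 + 15.0
        lfa = textured_plane_lightfield(small_geometry, za, seed=1)
        lfb = textured_plane_lightfield(small_geometry, zb, seed=2)
        nx = small_geometry.detector_pixels[0]
        images = np.where(
            (np.arange(nx) < nx // 2)[None, None, :], lfa.images, lfb.images
        )
        lf = LightField(images=images, geometry=small_geometry)
        zs = default_z_samples(small_geometry)
        cue = defocus_cue(focal_stack(lf, zs), z_ref=Z0)
        step = zs[1] - zs[0]
        left = np.median(cue.best_depth[16:-16, 10:nx // 2 - 10])
        right = np.median(cue.best_depth[16:-16, nx // 2 + 10:-10])
        assert abs(left - za) <= step + 1e-9
        assert abs(right - zb) <= step + 1e-9


class TestCorrespondenceCue:
    def test_bead_depth_recovered(self, bead_lightfield):
        lf = preprocess_branch(bead_lightfield)
        zs = default_z_samples(lf.geometry)
        cue = correspondence_cue(lf, zs, z_ref=Z0)
        nx, ny = lf.geometry.detector_pixels
        pitch = lf.geometry.effective_pixel * 1e-3
        col = int(round(1.0 / pitch + (nx - 1) / 2))
        row = int(round(-0.5 / pitch + (ny - 1) / 2))
        step = zs[1] - zs[0]
        assert abs(cue.best_depth[row, col] - BEAD_Z) <= step + 1e-9
        assert cue.confidence[row, col] > 0.3

    def test_noisy_bead_within_one_step(self, small_geometry, bead_phantom):
        from xlfemu.projector import AcquisitionSettings, acquire_lightfield

        lf_raw = acquire_lightfield(
            bead_phantom, small_geometry,
            AcquisitionSettings(photons_per_pixel=1e4, noise=True, seed=5),
        )
        lf = preprocess_branch(lf_raw)
        zs = default_z_samples(small_geometry)
        cue = correspondence_cue(lf, zs, z_ref=Z0)
        nx, ny = small_geometry.detector_pixels
        pitch = small_geometry.effective_pixel * 1e-3
        col = int(round(1.0 / pitch + (nx - 1) / 2))
        row = int(round(-0.5 / pitch + (ny - 1) / 2))
        step = zs[1] - zs[0]
        assert abs(cue.best_depth[row, col] - BEAD_Z) <= step + 1e-9

    def test_uniform_lightfield_zero_confidence(self, small_geometry):
        n = small_geometry.n_views
        nx, ny = small_geometry.detector_pixels
        lf = LightField(images=np.full((n, ny, nx), 5.0),
                        geometry=small_geometry)
        zs = np.linspace(Z0 - 10, Z0 + 10, 5)
        cue = correspondence_cue(lf, zs, z_ref=Z0)
        assert np.allclose(cue.confidence, 0.0)


def synthetic_cues(zd, zc, cd, cc, z_samples):
    zd, zc = np.asarray(zd, float), np.asarray(zc, float)
    shape = (len(z_samples),) + zd.shape
    return (
        CueResponse("defocus", np.zeros(shape), np.asarray(z_samples, float),
                    zd, np.asarray(cd, float)),
        CueResponse("correspondence", np.zeros(shape),
                    np.asarray(z_samples, float), zc, np.asarray(cc, float)),
    )


class TestMergeCues:
    z_samples = np.arange(0.0, 11.0)

    def test_unregularized_closed_form_average(self):
        rng = np.random.default_rng(3)
        zd = rng.uniform(2, 8, size=(16, 16))
        zc = rng.uniform(2, 8, size=(16, 16))
        ones = np.ones((16, 16))
        d, c = synthetic_cues(zd, zc, ones, ones, self.z_samples)
        out = merge_cues(d, c, lam_grad=0.0, lam_lap=0.0, n_iter=50)
        assert np.allclose(out.depth, (zd + zc) / 2, atol=1e-9)

    def test_strong_regularization_flattens(self):
        zd = np.full((16, 16), 2.0)
        zd[:, 8:] = 8.0
        ones = np.ones((16, 16))
        d, c = synthetic_cues(zd, zd, ones, ones, self.z_samples)
        out = merge_cues(d, c, lam_grad=100.0, lam_lap=100.0, n_iter=5000)
        assert np.nanstd(out.depth) < 0.2

    def test_objective_monotone_decrease(self):
        rng = np.random.default_rng(4)
        zd = rng.uniform(0, 10, size=(24, 24))
        zc = zd + rng.normal(scale=1.0, size=zd.shape)
        conf = rng.uniform(0.2, 1.0, size=zd.shape)
        d, c = synthetic_cues(zd, zc, conf, conf, self.z_samples)
        out = merge_cues(d, c, lam_grad=0.5, lam_lap=0.5, n_iter=200)
        obj = np.array(out.meta["objective"])
        assert np.all(np.diff(obj) <= 1e-12 * obj[0])
        assert obj[-1] < 0.9 * obj[0]

    def test_denoising_beats_raw_cues(self):
        """On a noisy single plane the merged map is closer to the truth
        than either raw cue map."""
        rng = np.random.default_rng(5)
        truth = 5.0
        zd = truth + rng.normal(scale=1.5, size=(32, 32))
        zc = truth + rng.normal(scale=1.5, size=(32, 32))
        ones = np.ones((32, 32))
        d, c = synthetic_cues(zd, zc, ones, ones, self.z_samples)
        out = merge_cues(d, c, lam_grad=2.0, lam_lap=0.5, n_iter=300)
        err_merged = np.median(np.abs(out.depth - truth))
        err_raw = np.median(np.abs(zd - truth))
        assert err_merged < err_raw
        assert err_merged < 1.0  # under one depth step

    def test_all_zero_confidence_invalid(self):
        zeros = np.zeros((8, 8))
        d, c = synthetic_cues(zeros, zeros, zeros, zeros, self.z_samples)
        out = merge_cues(d, c)
        assert not out.valid.any()
        assert np.isnan(out.depth).all()

    def test_depths_stay_within_stack_range(self):
        rng = np.random.default_rng(6)
        zd = rng.uniform(0, 10, size=(12, 12))
        d, c = synthetic_cues(zd, zd, np.ones_like(zd), np.ones_like(zd),
                              self.z_samples)
        out = merge_cues(d, c, lam_grad=5.0, lam_lap=5.0, n_iter=100)
        ok = out.valid
        assert np.all(out.depth[ok] >= self.z_samples[0] - 1e-9)
        assert np.all(out.depth[ok] <= self.z_samples[-1] + 1e-9)


class TestEstimateDepthmap:
    def test_bead_depth_end_to_end(self, bead_lightfield):
        lf = preprocess_branch(bead_lightfield)
        zs = default_z_samples(lf.geometry)
        dmap = estimate_depthmap(lf, z_samples=zs, n_iter=150)
        assert dmap.valid.any()
        step = zs[1] - zs[0]
        est = np.nanmedian(dmap.depth[dmap.valid])
        assert abs(est - BEAD_Z) <= step + 1e-9

    def test_intensity_scaling_invariance(self, bead_lightfield):
        lf = preprocess_branch(bead_lightfield)
        zs = default_z_samples(lf.geometry)
        a = estimate_depthmap(lf, z_samples=zs, n_iter=60)
        scaled = dataclasses.replace(lf, images=lf.images * 7.5)
        b = estimate_depthmap(scaled, z_samples=zs, n_iter=60)
        assert np.array_equal(a.valid, b.valid)
        assert np.allclose(a.depth[a.valid], b.depth[b.valid], atol=1e-6)

    def test_empty_lightfield_all_invalid(self, small_geometry):
        n = small_geometry.n_views
        nx, ny = small_geometry.detector_pixels
        lf = LightField(images=np.zeros((n, ny, nx)),
                        geometry=small_geometry)
        zs = np.linspace(Z0 - 10, Z0 + 10, 5)
        with pytest.warns(UserWarning):
            dmap = estimate_depthmap(lf, z_samples=zs, n_iter=10)
        assert not dmap.valid.any()
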