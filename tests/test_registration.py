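"""Histogram matching, demons registration, warping and similarity metrics."""

import numpy as np
import pytest

from drrmatch.imaging_io import Image2D
from drrmatch.registration import (
    DemonsParams,
    DisplacementField,
    corr,
    demons_register,
    histogram_match,
    ssim,
    warp_image,
)


def gaussian_blob(shape=(64, 64), center=(32, 32), sigma=8.0, amp=1.0):
    r, c = np.mgrid[: shape[0], : shape[1]].astype(float)
    return amp * np.exp(-(((r - center[0]) ** 2 + (c - center[1]) ** 2) / (2 * sigma**2)))


def empirical_cdf(vals, grid):
    v = np.sort(vals.ravel())
    return np.searchsorted(v, grid, side="right") / v.size


# ----- histogram matching ----------------------------------------------------

class TestHistogramMatch:
    def test_self_match_within_one_level(self, rng):
        x = Image2D(rng.random((64, 64)))
        out = histogram_match(x, x, bins=256)
        assert np.max(np.abs(out.values - x.values)) <= 1.0 / 256 + 1e-12

    def test_binary_input_maps_to_reference_quantiles(self, rng):
        vals = np.zeros((64, 64))
        vals[:32] = 1.0  # 50/50 split
        ref = Image2D(rng.random((200, 200)))
        out = histogram_match(Image2D(vals), ref, bins=256).values
        levels = np.unique(out)
        assert len(levels) == 2
        # the two output levels are the reference's median and maximum quantiles
        assert abs(levels[0] - np.quantile(ref.values, 0.5)) < 0.02
        assert abs(levels[1] - np.quantile(ref.values, 1.0)) < 0.02

    def test_output_cdf_tracks_reference_cdf(self, rng):
        x = Image2D(rng.random((100, 100)))
        ref = Image2D(rng.beta(2, 5, size=(100, 100)))
        out = histogram_match(x, ref, bins=256).values
        grid = np.linspace(ref.values.min(), ref.values.max(), 512)
        sup = np.max(np.abs(empirical_cdf(out, grid) - empirical_cdf(ref.values, grid)))
        assert sup <= 2.0 / 256

    def test_output_range_within_reference_range(self, rng):
        x = Image2D(rng.normal(5, 2, size=(50, 50)))
        ref = Image2D(rng.random((50, 50)) * 0.5 + 0.25)
        out = histogram_match(x, ref).values
        assert out.min() >= ref.values.min() - 1e-12
        assert out.max() <= ref.values.max() + 1e-12

    def test_matches_skimage_reference_implementation(self, rng):
        from skimage.exposure import match_histograms

        x = rng.random((80, 80))
        ref = rng.beta(5, 2, size=(80, 80))
        ours = histogram_match(Image2D(x), Image2D(ref), bins=1024).values
        theirs = match_histograms(x, ref)
        assert np.mean(np.abs(ours - theirs)) < 0.01

    def test_constant_images_rejected(self, rng):
        const = Image2D(np.full((8, 8), 0.5))
        x = Image2D(rng.random((8, 8)))
        with pytest.raises(ValueError):
            histogram_match(const, x)
        with pytest.raises(ValueError):
            histogram_match(x, const)


# ----- warping ---------------------------------------------------------------

class TestWarp:
    def test_zero_field_is_identity(self, rng):
        img = Image2D(rng.random((16, 16)))
        fld = DisplacementField(np.zeros((2, 16, 16)))
        np.testing.assert_array_equal(warp_image(img, fld).values, img.values)

    def test_constant_unit_column_shift(self, rng):
        img = Image2D(rng.random((16, 16)))
        u = np.zeros((2, 16, 16))
        u[1] = 1.0  # sample one column to the right
        out = warp_image(img, DisplacementField(u)).values
        np.testing.assert_allclose(out[:, :-1], img.values[:, 1:], atol=1e-12)

    def test_interpolation_preserves_bounds(self, rng):
        img = Image2D(rng.random((16, 16)))
        u = rng.normal(0, 3, size=(2, 16, 16))
        out = warp_image(img, DisplacementField(u)).values
        assert out.min() >= img.values.min() - 1e-12
        assert out.max() <= img.values.max() + 1e-12

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            warp_image(Image2D(rng.random((8, 8))), DisplacementField(np.zeros((2, 9, 9))))


# ----- demons ----------------------------------------------------------------

class TestDemons:
    def test_identical_images_yield_null_field(self, rng):
        img = Image2D(gaussian_blob() + 0.01 * rng.random((64, 64)))
        res = demons_register(img, img)
        assert np.max(res.field.magnitude()) <= 1e-3
        np.testing.assert_allclose(res.warped.values, img.values, atol=1e-6)

    def test_recovers_known_translation(self):
        fixed = Image2D(gaussian_blob(center=(32, 32)))
        moving = Image2D(gaussian_blob(center=(35, 32)))  # content 3 rows below
        res = demons_register(moving, fixed)
        # backward-warp convention: sampling moving at +3 rows restores fixed
        core = fixed.values >= 0.5 * fixed.values.max()
        epe = np.hypot(res.field.u[0] - 3.0, res.field.u[1] - 0.0)
        assert epe[core].mean() <= 1.0

    def test_registration_chain_improves_similarity_on_distorted_pair(self, default_phantom):
        # the cross-modality chain: histogram matching then demons.  Without
        # the intensity normalisation, SSD-driven demons trades geometry for
        # intensity on a gamma-distorted pair and correlation can drop.
        from drrmatch.matchfinder import _normalize01
        from drrmatch.phantom import XraySimSpec, make_reference_xray
        from drrmatch.projection import mip_project, resample_isotropic, rotate_volume

        ref = make_reference_xray(default_phantom, XraySimSpec(true_angle_deg=5.0, seed=7))
        drr = resample_isotropic(mip_project(rotate_volume(default_phantom, 8.0)))
        moving = Image2D(_normalize01(drr.values, clip_percentiles=None))
        res = demons_register(histogram_match(moving, ref), ref)
        assert res.corr > corr(moving, ref)

    def test_never_worsens_mean_absolute_mismatch(self, rng):
        fixed = Image2D(gaussian_blob(center=(30, 34)))
        moving = Image2D(gaussian_blob(center=(33, 31)))
        res = demons_register(moving, fixed)
        before = np.abs(moving.values - fixed.values).mean()
        after = np.abs(res.warped.values - fixed.values).mean()
        assert after <= before

    def test_deterministic_bit_identical(self, rng):
        fixed = Image2D(rng.random((32, 32)))
        moving = Image2D(rng.random((32, 32)))
        p = DemonsParams(iterations_per_level=(10, 5), pyramid_levels=2)
        r1 = demons_register(moving, fixed, p)
        r2 = demons_register(moving, fixed, p)
        assert np.array_equal(r1.field.u, r2.field.u)
        assert r1.ssim == r2.ssim and r1.corr == r2.corr

    def test_agrees_with_simpleitk_demons_on_translation(self):
        # independent reference implementation of the same diffusion scheme
        import SimpleITK as sitk

        fixed = gaussian_blob(center=(32, 32))
        moving = gaussian_blob(center=(35, 33))
        f = sitk.GetImageFromArray(fixed)
        m = sitk.GetImageFromArray(moving)
        dem = sitk.DemonsRegistrationFilter()
        dem.SetNumberOfIterations(200)
        dem.SetStandardDeviations(2.0)
        field = sitk.GetArrayFromImage(dem.Execute(f, m))  # (rows, cols, [x, y])
        ours = demons_register(Image2D(moving), Image2D(fixed))
        core = fixed >= 0.5 * fixed.max()
        # both should point at the (+3, +1) translation within a pixel on average
        theirs_epe = np.hypot(field[..., 1] - 3.0, field[..., 0] - 1.0)[core].mean()
        ours_epe = np.hypot(ours.field.u[0] - 3.0, ours.field.u[1] - 1.0)[core].mean()
        assert ours_epe <= 1.0
        assert abs(ours_epe - theirs_epe) <= 1.0

    def test_validation(self, rng):
        with pytest.raises(ValueError):
            demons_register(Image2D(rng.random((8, 8))), Image2D(rng.random((9, 9))))
        with pytest.raises(ValueError):
            DemonsParams(iterations_per_level=(10,), pyramid_levels=2)


# ----- metrics ---------------------------------------------------------------

class TestSSIM:
    def test_self_similarity_is_one(self, rng):
        x = Image2D(rng.random((32, 32)))
        assert abs(ssim(x, x) - 1.0) <= 1e-9

    def test_anticorrelated_checkerboard_strongly_negative(self):
        r, c = np.mgrid[:32, :32]
        x = ((r + c) % 2).astype(float)
        assert ssim(Image2D(x), Image2D(1.0 - x)) < -0.3

    def test_single_window_equals_direct_formula_on_toys(self, rng):
        for _ in range(10):
            x = rng.random((5, 5))
            y = rng.random((5, 5))
            # direct whole-image evaluation of the SSIM formula
            mx, my = x.mean(), y.mean()
            vx, vy = x.var(), y.var()
            cov = ((x - mx) * (y - my)).mean()
            c1, c2 = 0.01**2, 0.03**2
            expected = ((2 * mx * my + c1) * (2 * cov + c2)) / ((mx**2 + my**2 + c1) * (vx + vy + c2))
            assert abs(ssim(x, y, global_window=True) - expected) < 1e-12

    def test_symmetry(self, rng):
        x, y = Image2D(rng.random((32, 32))), Image2D(rng.random((32, 32)))
        assert ssim(x, y) == ssim(y, x)

    def test_invariant_to_joint_rescale(self, rng):
        # pure scaling with a consistently scaled dynamic range cancels in
        # every SSIM term (an intensity *offset* deliberately does not: the
        # luminance term compares absolute means)
        x, y = rng.random((32, 32)), rng.random((32, 32))
        base = ssim(x, y, data_range=1.0)
        scaled = ssim(100 * x, 100 * y, data_range=100.0)
        assert abs(base - scaled) < 1e-9

    def test_close_to_skimage_reference(self, rng):
        from skimage.metrics import structural_similarity

        x, y = rng.random((64, 64)), rng.random((64, 64))
        theirs = structural_similarity(
            x, y, gaussian_weights=True, sigma=1.5, use_sample_covariance=False, data_range=1.0
        )
        assert abs(ssim(x, y) - theirs) < 0.02


class TestCorr:
    def test_affine_pairs_exact(self, rng):
        # integer-valued pixels on power-of-two grids keep sums exact in
        # floating point, so perfect linearity must give exactly +-1
        for _ in range(20):
            x = rng.integers(0, 1000, size=(16, 16)).astype(float)
            assert corr(x, 2 * x + 3) == 1.0
            assert corr(x, -x) == -1.0

    def test_four_pixel_toy_hand_oracle(self):
        # Pearson by hand: dev products sum 3, each squared-dev sum 5 -> 0.6
        x = np.array([[0.0, 1.0], [2.0, 3.0]])
        y = np.array([[1.0, 0.0], [3.0, 2.0]])
        assert abs(corr(x, y) - 0.6) < 1e-12

    def test_invariant_to_positive_affine_rescale(self, rng):
        x, y = rng.random((16, 16)), rng.random((16, 16))
        assert abs(corr(x, y) - corr(3 * x + 1, y)) < 1e-12
        assert abs(corr(x, y) - corr(x, 0.1 * y - 5)) < 1e-12

    def test_constant_image_rejected(self, rng):
        with pytest.raises(ValueError):
            corr(np.full((8, 8), 2.0), rng.random((8, 8)))
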