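import numpy as np
import pytest
from scipy.integrate import quad

from frapkit.image_io import ImageSeries
from frapkit.profiling_recovery import (
    NoReferenceSignalError,
    RadialProfile,
    annulus_mask,
    average_and_offset_profiles,
    finalize_profile,
    radial_profile,
    recovery_curve,
    recovery_roi,
)

from conftest import make_frap_scene


def make_profile(values, spacing=0.028):
    values = np.asarray(values, dtype=float)
    radii = (np.arange(len(values)) + 0.5) * spacing
    return RadialProfile(radii_um=radii, mean_intensity=values, spacing_um=spacing)


class TestRadialProfile:
    def test_uniform_image_constant_rings(self):
        img = np.full((95, 95), 3.7)
        p = radial_profile(img, (4.8, 4.8), 0.105)
        finite = np.isfinite(p.mean_intensity)
        assert finite.any()
        np.testing.assert_allclose(p.mean_intensity[finite], 3.7)

    def test_single_bright_pixel_dominates_ring_zero(self):
        img = np.full((95, 95), 1.0)
        img[47, 47] = 1000.0
        center = (47 * 0.105, 47 * 0.105)
        p = radial_profile(img, center, 0.105)
        k0 = np.flatnonzero(np.isfinite(p.mean_intensity))[0]
        assert p.mean_intensity[k0] > 100
        later = p.mean_intensity[k0 + 1 :]
        np.testing.assert_allclose(later[np.isfinite(later)], 1.0)

    def test_default_grid_has_108_rings(self):
        img = np.ones((95, 95))
        p = radial_profile(img, (4.8, 4.8), 0.105)
        assert len(p.radii_um) == 108
        assert np.allclose(np.diff(p.radii_um), 0.028)

    def test_gaussian_matches_annulus_integral_oracle(self):
        # oracle: dense numeric integration of exp(-r^2 / 2 sigma^2) over
        # each annulus, compared at 2% of the peak
        px, sigma, s = 0.005, 0.4, 0.028
        n = 1201
        yy, xx = np.mgrid[0:n, 0:n]
        c = (n // 2) * px
        img = np.exp(-(((xx * px - c) ** 2 + (yy * px - c) ** 2)) / (2 * sigma**2))
        p = radial_profile(img, (c, c), px, spacing_um=s, extent_um=3.02)
        for k, measured in enumerate(p.mean_intensity):
            r0, r1 = k * s, (k + 1) * s
            num = quad(lambda r: np.exp(-(r**2) / (2 * sigma**2)) * r, r0, r1)[0]
            expected = num / ((r1**2 - r0**2) / 2)
            assert measured == pytest.approx(expected, abs=0.02)

    def test_rings_beyond_image_marked_missing(self):
        img = np.ones((11, 11))  # ~1 um wide; most of the 3.02 um extent is off-image
        p = radial_profile(img, (0.5, 0.5), 0.105)
        assert np.isnan(p.mean_intensity[-1])  # missing, not zero
        assert np.isfinite(p.mean_intensity).any()

    def test_center_outside_image_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            radial_profile(np.ones((10, 10)), (50.0, 0.5), 0.105)

    def test_rotation_invariance(self):
        # rotating the scene 90 degrees about the centre pixel leaves ring
        # means unchanged (pixel radii are preserved exactly)
        rng = np.random.default_rng(3)
        yy, xx = np.mgrid[0:95, 0:95]
        img = np.exp(-((xx - 47.0) ** 2 + (yy - 47.0) ** 2) / (2 * 8.0**2))
        img += rng.uniform(0, 0.02, img.shape)
        center = (47 * 0.105, 47 * 0.105)
        a = radial_profile(img, center, 0.105).mean_intensity
        b = radial_profile(np.rot90(img), center, 0.105).mean_intensity
        # boundary pixels can flip rings at float epsilon; differences stay
        # below 2% of the peak (discretisation only)
        np.testing.assert_allclose(a, b, atol=0.02 * np.nanmax(a))


class TestFinalizeProfile:
    def test_arithmetic_example(self):
        p = finalize_profile(make_profile([4.0, 2.0, 1.0]), cytosolic_background=1.0)
        np.testing.assert_allclose(p.mean_intensity, [1.0, 1 / 3, 0.0])
        np.testing.assert_allclose(p.mirrored_intensity, [0.0, 1 / 3, 1.0, 1 / 3, 0.0])
        np.testing.assert_allclose(
            p.mirrored_axis_um, [-0.056, -0.028, 0.0, 0.028, 0.056], atol=1e-12
        )
        assert p.background_subtracted and p.normalised

    def test_idempotent_on_normalised(self):
        p = finalize_profile(make_profile([1.0, 0.5, 0.25]), 0.0)
        q = finalize_profile(p, 0.0)
        np.testing.assert_allclose(q.mean_intensity, p.mean_intensity)

    def test_max_exactly_one(self, rng):
        for _ in range(20):
            vals = rng.uniform(0.1, 50.0, size=rng.integers(2, 30))
            p = finalize_profile(make_profile(vals), cytosolic_background=0.05)
            assert np.nanmax(p.mean_intensity) == 1.0

    def test_mirrored_exactly_symmetric(self, rng):
        vals = rng.uniform(0, 10, size=12)
        p = finalize_profile(make_profile(vals), 0.0)
        np.testing.assert_array_equal(p.mirrored_intensity, p.mirrored_intensity[::-1])
        np.testing.assert_array_equal(p.mirrored_axis_um, -p.mirrored_axis_um[::-1])

    def test_all_zero_after_subtraction_error(self):
        with pytest.raises(ValueError, match="no positive peak"):
            finalize_profile(make_profile([1.0, 1.0]), cytosolic_background=1.0)

    def test_negative_background_rejected(self):
        with pytest.raises(ValueError):
            finalize_profile(make_profile([1.0]), -0.1)

    def test_nan_rings_propagate_not_zero(self):
        p = finalize_profile(make_profile([2.0, np.nan, 1.0]), 0.0)
        assert np.isnan(p.mean_intensity[1])
        assert p.mean_intensity[0] == 1.0


class TestAverageAndOffset:
    def test_identical_profiles_offset_zero(self):
        profs = [finalize_profile(make_profile([4.0, 2.0, 1.0]), 1.0) for _ in range(10)]
        paired = average_and_offset_profiles(profs, profs, 0.0)
        np.testing.assert_allclose(paired.green_mean, profs[0].mirrored_intensity)
        np.testing.assert_allclose(paired.red_mean, profs[0].mirrored_intensity)
        np.testing.assert_array_equal(paired.green_axis_um, paired.red_axis_um)

    def test_offset_shifts_red_axis(self):
        profs = [finalize_profile(make_profile([1.0, 4.0, 2.0, 1.0]), 0.0)] * 10
        paired = average_and_offset_profiles(profs, profs, 0.21)
        g_peak = paired.green_axis_um[np.argmax(paired.green_mean)]
        r_peak = paired.red_axis_um[np.argmax(paired.red_mean)]
        assert r_peak - g_peak == pytest.approx(0.21)
        np.testing.assert_allclose(
            paired.red_axis_um - paired.green_axis_um, 0.21
        )

    def test_averaging_copies_is_identity(self):
        p = finalize_profile(make_profile([3.0, 2.0, 0.5]), 0.0)
        paired = average_and_offset_profiles([p] * 12, [p] * 12, 0.0)
        np.testing.assert_allclose(paired.green_mean, p.mirrored_intensity)

    def test_minimum_profile_count_enforced(self):
        p = finalize_profile(make_profile([2.0, 1.0]), 0.0)
        with pytest.raises(ValueError, match="10 required"):
            average_and_offset_profiles([p] * 9, [p] * 10, 0.0)
        # the floor is configurable
        average_and_offset_profiles([p], [p], 0.0, min_profiles=1)

    def test_mismatched_grids_error(self):
        a = finalize_profile(make_profile([2.0, 1.0]), 0.0)
        b = finalize_profile(make_profile([2.0, 1.0, 0.5]), 0.0)
        with pytest.raises(ValueError, match="grid"):
            average_and_offset_profiles([a] * 10, [b] * 10, 0.0)

    def test_unfinalized_profiles_rejected(self):
        raw = make_profile([2.0, 1.0])
        with pytest.raises(ValueError, match="finalized"):
            average_and_offset_profiles([raw] * 10, [raw] * 10, 0.0)


class TestRecoveryRoi:
    def test_constant_image_error(self):
        with pytest.raises(NoReferenceSignalError):
            recovery_roi(np.full((50, 50), 5.0))

    def test_single_hot_pixel(self):
        img = np.zeros((100, 100))
        img[40, 60] = 100.0
        mask = recovery_roi(img)
        assert mask.sum() == 1 and mask[40, 60]

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(5)
        yy, xx = np.mgrid[0:80, 0:80]
        img = 10 + 200 * np.exp(-((xx - 40) ** 2 + (yy - 40) ** 2) / (2 * 4.0**2))
        img = rng.poisson(img).astype(float)
        mask = recovery_roi(img)
        thr = img.mean() + 2 * img.std()
        expected = np.zeros_like(mask)
        for r in range(img.shape[0]):
            for c in range(img.shape[1]):
                expected[r, c] = img[r, c] > thr
        np.testing.assert_array_equal(mask, expected)

    def test_typical_roi_size_on_realistic_scene(self):
        series, spec, truth, center = make_frap_scene(42)
        from frapkit.image_io import max_project

        ref = max_project(series).pixels[0, 1, 0]  # red, pre-bleach
        mask = recovery_roi(ref)
        # roughly the (1.05 um)^2 ~ 10x10 px patch the 2 SD rule selects
        assert 20 <= mask.sum() <= 400


def constant_series(value=50.0, n_t=5):
    pixels = np.full((n_t, 2, 1, 40, 40), float(value))
    return ImageSeries(
        pixels=pixels,
        pixel_size_um=0.105,
        z_spacing_um=0.5,
        frame_times_s=list(np.arange(n_t, dtype=float) * 30 - 30),
        channel_names=["green", "red"],
        bleach_frame_index=1,
    )


class TestRecoveryCurve:
    def mask_and_bg(self):
        mask = np.zeros((40, 40), dtype=bool)
        mask[18:22, 18:22] = True
        bg = np.zeros((40, 40), dtype=bool)
        bg[:5] = True
        return mask, bg

    def test_constant_series_curve_is_one(self):
        s = constant_series()
        s.pixels[:, :, :, :5, :] = 10.0  # background region darker than ROI
        mask, bg = self.mask_and_bg()
        curve = recovery_curve(s, mask, bg)
        np.testing.assert_allclose(curve.green_norm, 1.0)
        np.testing.assert_allclose(curve.red_norm, 1.0)
        assert curve.roi_n_pixels == 16

    def test_bleached_to_background_stays_zero(self):
        s = constant_series()
        s.pixels[:, :, :, :5, :] = 10.0
        s.pixels[1:] = 10.0  # bleach to pure background, no recovery
        mask, bg = self.mask_and_bg()
        curve = recovery_curve(s, mask, bg)
        np.testing.assert_allclose(curve.green_norm[1:], 0.0, atol=1e-9)
        np.testing.assert_allclose(curve.green_norm[0], 1.0)

    def test_background_offset_invariance(self):
        series, spec, truth, center = make_frap_scene(11)
        from frapkit.localization_offset import window_around

        mask = np.zeros(spec.image_shape_px, dtype=bool)
        r0, r1, c0, c1 = window_around(center, 0.5, spec.pixel_size_um, spec.image_shape_px)
        mask[r0:r1, c0:c1] = True
        bg = annulus_mask(spec.image_shape_px, center, spec.pixel_size_um)
        base = recovery_curve(series, mask, bg)
        shifted = series
        shifted.pixels = series.pixels + 123.0
        curve = recovery_curve(shifted, mask, bg)
        np.testing.assert_allclose(curve.green_norm, base.green_norm, atol=1e-9)
        np.testing.assert_allclose(curve.red_norm, base.red_norm, atol=1e-9)

    def test_nonpositive_prebleach_error(self):
        s = constant_series(0.0)
        mask, bg = self.mask_and_bg()
        with pytest.raises(ValueError, match="pre-bleach"):
            recovery_curve(s, mask, bg)

    def test_empty_mask_error(self):
        s = constant_series()
        _, bg = self.mask_and_bg()
        with pytest.raises(ValueError, match="ROI mask"):
            recovery_curve(s, np.zeros((40, 40), dtype=bool), bg)

    def test_requires_bleach_index(self):
        s = constant_series()
        s.bleach_frame_index = None
        mask, bg = self.mask_and_bg()
        with pytest.raises(ValueError, match="bleach_frame_index"):
            recovery_curve(s, mask, bg)

    def test_delayed_red_recovery_matches_schedule(self):
        # oracle: the generator's closed-form schedule; green rises from the
        # first post-bleach frame, red stays flat until the programmed
        # transition, then rises
        series, spec, truth, center = make_frap_scene(
            12,
            frame_times=(-30.0, 0.0, 30.0, 60.0, 90.0, 120.0, 150.0),
            recovery_delay_frame=(None, 4),
            recovery_rate_per_s=(0.02, 0.03),
        )
        from frapkit.image_io import max_project

        ref = max_project(series).pixels[0, 1, 0]
        mask = recovery_roi(ref)
        bg = annulus_mask(spec.image_shape_px, center, spec.pixel_size_um)
        curve = recovery_curve(series, mask, bg)
        assert curve.green_norm[3] > 0.2  # 60 s post-bleach
        assert np.all(np.abs(curve.red_norm[1:4]) < 0.1)
        assert curve.red_norm[-1] > 0.15
        assert curve.red_norm[-1] > curve.red_norm[4] + 0.05


class TestAnnulusMask:
    def test_radius_bounds(self):
        mask = annulus_mask((96, 96), (4.8, 4.8), 0.105)
        yy, xx = np.mgrid[0:96, 0:96]
        r = np.hypot(xx * 0.105 - 4.8, yy * 0.105 - 4.8)
        assert np.all(r[mask] >= 1.8) and np.all(r[mask] < 2.4)
        assert mask.any()
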