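"""Preprocessing: calibration identities, inclusive band cropping,
Savitzky-Golay exactness, area normalization, segmentation, averaging,
derivatives and resizing."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from berryspec.cube import HyperCube
from berryspec.preprocess import (
    SegmentationError,
    Spectrum,
    area_normalize,
    calibrate_reflectance,
    crop_bands,
    first_derivative,
    mean_spectrum,
    preprocess_cube,
    resize_cube,
    segment_fruit,
    sg_smooth,
)
from berryspec.synthetic import PhantomConfig, simulate_phantom


def _cube(values, wl=None):
    values = np.asarray(values, dtype=float)
    wl = np.arange(values.shape[2], dtype=float) if wl is None else np.asarray(wl, dtype=float)
    return HyperCube(values, wl)


class TestCalibration:
    def setup_method(self):
        rng = np.random.default_rng(0)
        self.dark = _cube(rng.uniform(0.0, 0.1, (4, 5, 6)))
        self.white = _cube(self.dark.values + rng.uniform(0.5, 1.0, (4, 5, 6)))

    def test_raw_equals_white_gives_ones(self):
        out = calibrate_reflectance(self.white, self.white, self.dark)
        np.testing.assert_allclose(out.values, 1.0)

    def test_raw_equals_dark_gives_zeros(self):
        out = calibrate_reflectance(self.dark, self.white, self.dark)
        np.testing.assert_allclose(out.values, 0.0)

    def test_midpoint_gives_half(self):
        mid = _cube((self.white.values + self.dark.values) / 2)
        out = calibrate_reflectance(mid, self.white, self.dark)
        np.testing.assert_allclose(out.values, 0.5)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            calibrate_reflectance(self.white, self.white, _cube(np.zeros((4, 5, 7))))

    def test_dead_pixel_denominator_guarded(self):
        white = _cube(self.dark.values.copy())  # white == dark everywhere
        out = calibrate_reflectance(self.dark, white, self.dark)
        assert np.all(np.isfinite(out.values))


class TestCropBands:
    def test_inclusive_bounds(self):
        cube = _cube(np.arange(2 * 2 * 5, dtype=float).reshape(2, 2, 5), [430, 441, 500, 947, 960])
        out = crop_bands(cube, 441, 947)
        assert list(out.wavelengths) == [441, 500, 947]
        np.testing.assert_array_equal(out.values, cube.values[:, :, 1:4])

    def test_default_synthetic_grid_keeps_400_bands(self):
        wl = PhantomConfig().wavelengths
        cube = _cube(np.ones((2, 2, wl.size)), wl)
        assert crop_bands(cube).n_bands == 400

    def test_degenerate_single_band(self):
        cube = _cube(np.ones((2, 2, 3)), [400, 500, 600])
        out = crop_bands(cube, 500, 500)
        assert list(out.wavelengths) == [500]

    def test_empty_interval_rejected(self):
        cube = _cube(np.ones((2, 2, 3)), [400, 500, 600])
        with pytest.raises(ValueError):
            crop_bands(cube, 610, 690)


class TestSavitzkyGolay:
    def test_constant_unchanged(self):
        spec = Spectrum(np.full(30, 3.25), np.arange(30.0))
        np.testing.assert_allclose(sg_smooth(spec).values, 3.25, atol=1e-12)

    def test_polynomials_reproduced_exactly(self):
        x = np.arange(40.0)
        for coeffs in ([2.0, -1.0, 0.5], [1.0, 0.3, -0.02, 0.001]):
            y = np.polynomial.polynomial.polyval(x, coeffs)
            out = sg_smooth(Spectrum(y, x), window=11, polyorder=3)
            np.testing.assert_allclose(out.values, y, atol=1e-8)

    def test_interior_matches_per_point_polyfit_oracle(self):
        rng = np.random.default_rng(4)
        x = np.arange(60.0)
        y = np.sin(x / 6) + rng.normal(0, 0.1, x.size)
        window, poly = 11, 3
        out = sg_smooth(Spectrum(y, x), window, poly).values
        half = window // 2
        for i in range(half, x.size - half):
            w = slice(i - half, i + half + 1)
            fit = np.polynomial.polynomial.polyfit(x[w] - x[i], y[w], poly)
            assert abs(out[i] - fit[0]) < 1e-9

    def test_applied_along_spectral_axis_only(self):
        rng = np.random.default_rng(1)
        values = rng.normal(size=(3, 4, 30))
        out = sg_smooth(_cube(values))
        for r in range(3):
            for c in range(4):
                expected = sg_smooth(Spectrum(values[r, c], np.arange(30.0))).values
                np.testing.assert_allclose(out.values[r, c], expected)

    def test_invalid_window_rejected(self):
        spec = Spectrum(np.ones(30), np.arange(30.0))
        with pytest.raises(ValueError):
            sg_smooth(spec, window=10)
        with pytest.raises(ValueError):
            sg_smooth(spec, window=5, polyorder=5)

    def test_noise_variance_reduced(self):
        rng = np.random.default_rng(7)
        x = np.arange(100.0)
        smooth = np.exp(-((x - 50) ** 2) / 400)
        ratios = []
        for _ in range(100):
            noise = rng.normal(0, 0.05, x.size)
            filtered = sg_smooth(Spectrum(smooth + noise, x)).values
            ratios.append(noise.var() / np.var(filtered - smooth))
        assert np.mean(ratios) > 2


class TestAreaNormalize:
    def test_flat_spectrum(self):
        out = area_normalize(Spectrum(np.array([2.0, 2.0, 2.0, 2.0]), np.arange(4.0)))
        np.testing.assert_allclose(out.values, 0.25)

    @given(st.integers(1, 1000))
    @settings(max_examples=25, derandomize=True)
    def test_scale_invariance(self, scale):
        rng = np.random.default_rng(0)
        s = rng.uniform(0.1, 1.0, 20)
        a = area_normalize(Spectrum(s, np.arange(20.0))).values
        b = area_normalize(Spectrum(scale * s, np.arange(20.0))).values
        np.testing.assert_allclose(a, b, rtol=1e-12)

    def test_sums_to_one(self, rng):
        values = rng.uniform(0.01, 1.0, (5, 6, 30))
        out = area_normalize(_cube(values))
        np.testing.assert_allclose(out.values.sum(axis=2), 1.0, atol=1e-12)

    def test_nonpositive_sum_rejected(self):
        with pytest.raises(ValueError):
            area_normalize(Spectrum(np.array([1.0, -2.0, 0.5]), np.arange(3.0)))


class TestSegmentation:
    def test_recovers_phantom_mask_at_default_noise(self, small_phantom):
        _, ph = small_phantom
        mask = segment_fruit(ph.cube)
        inter = (mask & ph.fruit_mask).sum()
        union = (mask | ph.fruit_mask).sum()
        assert inter / union >= 0.99

    def test_noiseless_mask_exact(self):
        ph = simulate_phantom(PhantomConfig(red_fraction=0.3, noise_sd=0.0, n_bands=64))
        assert np.array_equal(segment_fruit(ph.cube), ph.fruit_mask)

    def test_background_only_cube_rejected(self):
        cube = _cube(np.full((10, 10, 20), 0.02))
        with pytest.raises(SegmentationError):
            segment_fruit(cube)


class TestMeanSpectrum:
    def test_uniform_cube(self):
        cube = _cube(np.full((4, 4, 6), 0.7))
        mask = np.ones((4, 4), dtype=bool)
        np.testing.assert_allclose(mean_spectrum(cube, mask).values, 0.7)

    def test_single_pixel_mask(self, rng):
        cube = _cube(rng.normal(size=(4, 4, 6)))
        mask = np.zeros((4, 4), dtype=bool)
        mask[2, 1] = True
        np.testing.assert_array_equal(mean_spectrum(cube, mask).values, cube.values[2, 1])

    def test_matches_double_loop_oracle(self, rng):
        cube = _cube(rng.normal(size=(5, 6, 8)))
        mask = rng.random((5, 6)) > 0.4
        acc = np.zeros(8)
        count = 0
        for r in range(5):
            for c in range(6):
                if mask[r, c]:
                    acc += cube.values[r, c]
                    count += 1
        np.testing.assert_allclose(mean_spectrum(cube, mask).values, acc / count)

    def test_empty_mask_rejected(self):
        cube = _cube(np.ones((3, 3, 4)))
        with pytest.raises(ValueError):
            mean_spectrum(cube, np.zeros((3, 3), dtype=bool))


class TestFirstDerivative:
    def test_linear_spectrum_constant_slope(self):
        wl = np.linspace(400, 900, 50)
        out = first_derivative(Spectrum(0.002 * wl + 1.0, wl))
        np.testing.assert_allclose(out.values, 0.002, atol=1e-10)

    def test_constant_spectrum_zero(self):
        wl = np.linspace(400, 900, 50)
        np.testing.assert_allclose(first_derivative(Spectrum(np.full(50, 0.4), wl)).values, 0.0, atol=1e-12)

    def test_quadratic_matches_analytic(self):
        wl = np.linspace(0, 10, 60)
        out = first_derivative(Spectrum(wl**2, wl))
        np.testing.assert_allclose(out.values[5:-5], 2 * wl[5:-5], atol=1e-8)

    def test_single_band_rejected(self):
        with pytest.raises(ValueError):
            first_derivative(Spectrum(np.array([1.0]), np.array([500.0])))


class TestResize:
    def test_constant_preserved(self):
        cube = _cube(np.full((20, 20, 5), 0.3))
        out = resize_cube(cube, 85, 85)
        assert out.shape == (85, 85, 5)
        np.testing.assert_allclose(out.values, 0.3, atol=1e-12)

    def test_identity_resize_exact(self, rng):
        cube = _cube(rng.normal(size=(12, 14, 6)))
        out = resize_cube(cube, 12, 14)
        np.testing.assert_allclose(out.values, cube.values, atol=1e-12)

    def test_invalid_dims_rejected(self):
        with pytest.raises(ValueError):
            resize_cube(_cube(np.ones((4, 4, 3))), 0, 4)


class TestPipelineInvariants:
    def test_crop_commutes_with_spatial_average(self, small_phantom, rng):
        _, ph = small_phantom
        mask = ph.fruit_mask
        a = mean_spectrum(crop_bands(ph.cube), mask).values
        full = mean_spectrum(ph.cube, mask)
        keep = (full.wavelengths >= 441 - 1e-9) & (full.wavelengths <= 947 + 1e-9)
        np.testing.assert_array_equal(a, full.values[keep])

    def test_rerun_is_bit_identical(self, small_phantom):
        _, ph = small_phantom
        a = preprocess_cube(ph.cube)
        b = preprocess_cube(ph.cube)
        assert np.array_equal(a.values, b.values)

    def test_normalization_absorbs_per_pixel_scaling(self, rng):
        values = rng.uniform(0.1, 1.0, (4, 4, 30))
        scales = rng.uniform(0.5, 2.0, (4, 4, 1))
        a = area_normalize(sg_smooth(_cube(values)))
        b = area_normalize(sg_smooth(_cube(values * scales)))
        np.testing.assert_allclose(a.values, b.values, rtol=1e-10)

    def test_alternate_order_available(self, small_phantom):
        _, ph = small_phantom
        out = preprocess_cube(ph.cube, normalize_first=True)
        assert out.n_bands == 49
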