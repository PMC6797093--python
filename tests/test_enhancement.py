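"""Unit and property tests for the vegetation-enhancement transforms."""

import logging

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

import bananacount as bc
from bananacount.enhancement import (
    SCTSpec,
    StretchSpec,
    linear_contrast_stretch,
    synthetic_color_transform,
    tgi_broadband,
    tgi_narrowband,
    to_eight_bit,
)

bands = hnp.arrays(
    np.uint8, hnp.array_shapes(min_dims=2, max_dims=2, min_side=2, max_side=20)
)


def _img(arr):
    return bc.RasterImage(np.asarray(arr, dtype=np.uint8))


class TestLinearContrastStretch:
    def test_full_range_band_is_identity_at_zero_saturation(self):
        band = np.arange(256, dtype=np.uint8).reshape(16, 16)
        out = linear_contrast_stretch(_img(band), StretchSpec(0.0))
        np.testing.assert_array_equal(out.pixels, band)

    def test_small_band_closed_form_mapping(self):
        out = linear_contrast_stretch(_img([[10, 20, 30, 40, 50]]), StretchSpec(0.0))
        np.testing.assert_array_equal(out.pixels, [[0, 64, 128, 191, 255]])

    def test_constant_band_unchanged_with_warning(self, caplog):
        with caplog.at_level(logging.WARNING):
            out = linear_contrast_stretch(_img([[7, 7], [7, 7]]), StretchSpec(0.01))
        np.testing.assert_array_equal(out.pixels, 7)
        assert any("degenerate" in r.message for r in caplog.records)

    def test_output_variant_tag(self, rgb_ramp):
        assert linear_contrast_stretch(rgb_ramp).variant_tag == "LCS"

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(band=bands, sat=st.floats(0.0, 0.2))
    def test_monotone_per_band(self, band, sat):
        out = linear_contrast_stretch(_img(band), StretchSpec(sat)).pixels
        order = np.argsort(band, axis=None, kind="stable")
        gl_sorted = out.flatten()[order]
        assert np.all(np.diff(gl_sorted.astype(int)) >= 0)

    def test_saturation_clips_expected_pixel_fraction(self):
        rng = np.random.default_rng(0)
        band = rng.permutation(np.arange(256)).reshape(16, 16).astype(np.uint8)
        s = 0.05
        out = linear_contrast_stretch(_img(band), StretchSpec(s)).pixels
        n = band.size
        assert np.sum(out == 0) >= int(s * n)
        assert np.sum(out == 255) >= int(s * n)

    def test_invalid_saturation_rejected(self):
        with pytest.raises(ValueError):
            StretchSpec(0.5)


class TestSyntheticColorTransform:
    def test_constant_band_gives_black_output(self, caplog):
        with caplog.at_level(logging.WARNING):
            out = synthetic_color_transform(_img(np.full((30, 30), 42)))
        assert out.pixels.shape == (30, 30, 3)
        np.testing.assert_array_equal(out.pixels, 0)

    def test_output_range_and_band_count(self):
        rng = np.random.default_rng(1)
        band = rng.integers(0, 256, size=(64, 64)).astype(np.uint8)
        out = synthetic_color_transform(_img(band), SCTSpec(lowpass_sigma_px=5))
        assert out.n_bands == 3 and out.pixels.dtype == np.uint8

    def test_invariant_under_global_additive_offset(self):
        rng = np.random.default_rng(2)
        band = rng.integers(50, 150, size=(48, 48)).astype(np.uint8)
        a = synthetic_color_transform(_img(band), SCTSpec(lowpass_sigma_px=4))
        b = synthetic_color_transform(_img(band + 20), SCTSpec(lowpass_sigma_px=4))
        np.testing.assert_array_equal(a.pixels, b.pixels)

    def test_rejects_multiband_input(self, rgb_ramp):
        with pytest.raises(ValueError):
            synthetic_color_transform(rgb_ramp)


class TestTGI:
    @pytest.mark.parametrize(
        "rgb,expected",
        [((100, 100, 100), 0.0), ((0, 255, 0), 255.0), ((255, 0, 0), -99.45)],
    )
    def test_broadband_pixel_values(self, rgb, expected):
        px = np.array([[rgb]], dtype=np.uint8)
        assert tgi_broadband(bc.RasterImage(px)).values[0, 0] == pytest.approx(expected)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(band=bands)
    def test_broadband_zero_on_any_grayscale(self, band):
        gray = np.stack([band] * 3, axis=-1)
        np.testing.assert_allclose(tgi_broadband(bc.RasterImage(gray)).values, 0.0)

    def test_broadband_linearity(self):
        rng = np.random.default_rng(3)
        px = (2 * rng.integers(0, 128, size=(8, 8, 3))).astype(np.uint8)
        half = (px // 2).astype(np.uint8)
        np.testing.assert_allclose(
            tgi_broadband(bc.RasterImage(half)).values,
            0.5 * tgi_broadband(bc.RasterImage(px)).values,
        )

    def test_rejects_single_band(self):
        with pytest.raises(ValueError):
            tgi_broadband(_img(np.zeros((4, 4))))

    @pytest.mark.parametrize(
        "refl,expected",
        [((0.1, 0.1, 0.1), 0.0), ((0.05, 0.12, 0.04), 7.25)],
    )
    def test_narrowband_values(self, refl, expected):
        assert tgi_narrowband(*refl) == pytest.approx(expected)

    def test_narrowband_linearity_and_precondition(self):
        assert tgi_narrowband(0.1, 0.24, 0.08) == pytest.approx(2 * tgi_narrowband(0.05, 0.12, 0.04))
        with pytest.raises(ValueError):
            tgi_narrowband(-0.1, 0.1, 0.1)


class TestToEightBit:
    def test_fixed_range_midpoint_and_endpoints(self):
        band = bc.SignedBand(np.array([[0.0, 255.0, -255.0]]))
        np.testing.assert_array_equal(
            to_eight_bit(band, "fixed_range").pixels, [[128, 255, 0]]
        )

    def test_minmax_preserves_ordering(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(size=(12, 12)) * 80
        out = to_eight_bit(bc.SignedBand(vals)).pixels.astype(float)
        i, j = np.unravel_index([vals.argmin(), vals.argmax()], vals.shape)
        flat_v, flat_o = vals.flatten(), out.flatten()
        order = np.argsort(flat_v, kind="stable")
        assert np.all(np.diff(flat_o[order]) >= 0)

    def test_constant_band_maps_to_midgray_with_warning(self, caplog):
        with caplog.at_level(logging.WARNING):
            out = to_eight_bit(bc.SignedBand(np.full((3, 3), 5.0)))
        np.testing.assert_array_equal(out.pixels, 128)
        assert any("constant" in r.message for r in caplog.records)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            to_eight_bit(bc.SignedBand(np.zeros((2, 2))), "bogus")
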