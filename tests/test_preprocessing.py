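"""Preprocessing chain: green channel, FOV mask, denoise, equalize, gamma."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import ndimage

from retseg.errors import ChannelCountError, DegenerateImageError, ParameterError
from retseg.preprocessing import (
    compute_histogram,
    estimate_fov_mask,
    extract_green_channel,
    gamma_transform,
    gaussian_denoise,
    gaussian_kernel,
    masked_hist_equalize,
    preprocess,
)
from retseg.types import INTEGER, NORMALIZED, FundusImage, GrayImage


def _rgb(r, g, b, shape=(8, 8)):
    img = np.zeros(shape + (3,), dtype=np.uint8)
    img[..., 0], img[..., 1], img[..., 2] = r, g, b
    return FundusImage(pixels=img)


class TestGreenChannel:
    def test_projects_green_values(self):
        img = _rgb(10, 200, 30)
        out = extract_green_channel(img)
        assert out.convention == INTEGER and out.L == 256
        assert (out.values == 200).all()

    @pytest.mark.parametrize(
        "rgb,expected", [((255, 0, 0), 0), ((0, 255, 0), 255), ((0, 0, 255), 0)]
    )
    def test_pure_channels(self, rgb, expected):
        assert (extract_green_channel(_rgb(*rgb)).values == expected).all()

    def test_rejects_non_rgb(self):
        bad = FundusImage.__new__(FundusImage)
        bad.pixels = np.zeros((8, 8), dtype=np.uint8)
        bad.fov_mask = bad.truth = None
        with pytest.raises(ChannelCountError):
            extract_green_channel(bad)

    def test_returns_copy(self):
        img = _rgb(0, 7, 0)
        out = extract_green_channel(img)
        out.values[0, 0] = 99
        assert img.pixels[0, 0, 1] == 7


class TestFovMask:
    def test_supplied_mask_passthrough(self):
        mask = np.zeros((8, 8), dtype=np.uint8)
        mask[2:6, 2:6] = 1
        img = FundusImage(pixels=np.zeros((8, 8, 3), dtype=np.uint8), fov_mask=mask)
        assert (estimate_fov_mask(img) == mask).all()

    def test_estimates_disc(self, synth_small):
        bare = FundusImage(pixels=synth_small.pixels)
        est = estimate_fov_mask(bare)
        true = synth_small.fov_mask
        overlap = (est & true).sum() / true.sum()
        assert overlap >= 0.99

    def test_all_black_degenerate(self):
        img = FundusImage(pixels=np.zeros((16, 16, 3), dtype=np.uint8))
        with pytest.raises(DegenerateImageError):
            estimate_fov_mask(img)


class TestGaussianDenoise:
    def test_constant_preserved(self):
        g = GrayImage(np.full((10, 10), 37, dtype=np.uint8))
        assert (gaussian_denoise(g).values == 37).all()

    def test_single_pixel_spreads_vs_direct_convolution(self):
        vals = np.zeros((9, 9), dtype=np.int64)
        vals[4, 4] = 255
        out = gaussian_denoise(GrayImage(vals), size=3, sigma=1.0)
        k = gaussian_kernel(3, 1.0)
        expected = ndimage.convolve(vals.astype(float), k, mode="reflect")
        assert np.abs(out.values - expected).max() <= 0.5 + 1e-9
        # mass conserved up to rounding of 9 cells
        assert abs(int(out.values.sum()) - 255) <= 9

    def test_tiny_sigma_is_identity(self):
        vals = np.arange(64, dtype=np.int64).reshape(8, 8)
        out = gaussian_denoise(GrayImage(vals), size=3, sigma=1e-6)
        assert (out.values == vals).all()

    def test_bad_sigma(self):
        with pytest.raises(ParameterError):
            gaussian_denoise(GrayImage(np.zeros((4, 4), dtype=int)), sigma=0.0)


class TestHistogram:
    def test_direct_counts(self):
        g = GrayImage(np.array([[0, 0], [1, 2]]), L=4)
        h = compute_histogram(g, np.ones((2, 2)))
        assert h.counts.tolist() == [2, 1, 1, 0] and h.n == 4

    def test_mask_restricts_counts(self):
        g = GrayImage(np.array([[0, 0], [1, 2]]), L=4)
        mask = np.array([[1, 1], [0, 0]])
        h = compute_histogram(g, mask)
        assert h.counts.tolist() == [2, 0, 0, 0] and h.n == 2

    @given(st.integers(0, 2**32 - 1))
    def test_probabilities_sum_to_one(self, seed):
        r = np.random.default_rng(seed)
        g = GrayImage(r.integers(0, 256, (12, 12)))
        h = compute_histogram(g, np.ones((12, 12)))
        assert h.probabilities.sum() == pytest.approx(1.0)

    def test_empty_mask(self):
        with pytest.raises(DegenerateImageError):
            compute_histogram(GrayImage(np.zeros((4, 4), dtype=int)), np.zeros((4, 4)))


class TestEqualize:
    def test_constant_region_maps_to_top_level(self):
        g = GrayImage(np.full((4, 4), 93, dtype=np.int64))
        out = masked_hist_equalize(g, np.ones((4, 4)))
        assert (out.values == 255).all()

    def test_four_level_worked_example(self):
        # four masked pixels at levels 0, 63, 127, 255 -> 64, 128, 191, 255
        g = GrayImage(np.array([[0, 63], [127, 255]], dtype=np.int64))
        out = masked_hist_equalize(g, np.ones((2, 2)))
        assert out.values.tolist() == [[64, 128], [191, 255]]

    def test_outside_mask_set_to_zero(self):
        vals = np.full((4, 4), 100, dtype=np.int64)
        mask = np.zeros((4, 4))
        mask[:2] = 1
        out = masked_hist_equalize(GrayImage(vals), mask)
        assert (out.values[2:] == 0).all() and (out.values[:2] == 255).all()

    @given(st.integers(0, 2**32 - 1))
    def test_mapping_is_monotone(self, seed):
        r = np.random.default_rng(seed)
        g = GrayImage(r.integers(0, 256, (16, 16)))
        out = masked_hist_equalize(g, np.ones((16, 16)))
        order = np.argsort(g.values.ravel(), kind="stable")
        mapped = out.values.ravel()[order]
        assert (np.diff(mapped.astype(np.int64)) >= 0).all()

    def test_output_cdf_closer_to_uniform(self, synth_small):
        g = extract_green_channel(synth_small)
        mask = synth_small.fov_mask
        assert mask.sum() >= 1000
        out = masked_hist_equalize(g, mask)

        def cdf_dev(img):
            h = compute_histogram(img, mask)
            cdf = np.cumsum(h.probabilities)
            uniform = (np.arange(img.L) + 1) / img.L
            return np.abs(cdf - uniform).max()

        assert cdf_dev(out) <= cdf_dev(g) + 1e-12


class TestGamma:
    def test_endpoints_fixed(self):
        g = GrayImage(np.array([[0.0, 1.0]]), NORMALIZED)
        out = gamma_transform(g, gamma=2.7)
        assert out.values.tolist() == [[0.0, 1.0]]

    def test_gamma_one_is_identity(self):
        vals = np.linspace(0, 1, 11).reshape(1, 11)
        out = gamma_transform(GrayImage(vals, NORMALIZED), gamma=1.0)
        assert np.allclose(out.values, vals)

    def test_midpoint_value(self):
        out = gamma_transform(GrayImage(np.array([[0.5]]), NORMALIZED), gamma=1.3)
        assert out.values[0, 0] == pytest.approx(0.5**1.3, abs=1e-12)

    def test_darkens_or_brightens_midtones(self):
        vals = np.linspace(0.05, 0.95, 10).reshape(1, 10)
        g = GrayImage(vals, NORMALIZED)
        assert (gamma_transform(g, gamma=1.3).values <= vals).all()
        assert (gamma_transform(g, gamma=0.7).values >= vals).all()

    def test_integer_input_normalized_first(self):
        out = gamma_transform(GrayImage(np.array([[255]], dtype=np.int64)))
        assert out.convention == NORMALIZED and out.values[0, 0] == pytest.approx(1.0)

    def test_bad_gamma(self):
        with pytest.raises(ParameterError):
            gamma_transform(GrayImage(np.zeros((2, 2))), gamma=0.0)


class TestFullChain:
    def test_output_range_and_shape(self, synth_small):
        out = preprocess(synth_small)
        assert out.convention == NORMALIZED
        assert out.shape == synth_small.shape
        assert out.values.min() >= 0.0 and out.values.max() <= 1.0

    def test_deterministic(self, synth_small):
        a = preprocess(synth_small)
        b = preprocess(synth_small)
        assert (a.values == b.values).all()

    def test_contrast_not_decreased_in_fov(self, synth_small):
        green = extract_green_channel(synth_small).as_normalized()
        out = preprocess(synth_small)
        m = synth_small.fov_mask > 0
        assert out.values[m].std() >= green.values[m].std()
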