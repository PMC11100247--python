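"""Perceptual fusion: weight families, normalization, weighted sum."""

import numpy as np
import pytest

import oracles
from cbctfuse.core import PipelineConfig
from cbctfuse.fusion import (
    combine_weights,
    fuse,
    gradient_weights,
    intensity_weights,
    perceptual_fusion,
)

from conftest import random_image


class TestIntensityWeights:
    def test_sigma_rule_for_two_images(self):
        a = np.full((4, 4), 0.3)
        b = np.full((4, 4), 0.7)
        _, means, sigmas = intensity_weights([a, b])
        assert means == [pytest.approx(0.3), pytest.approx(0.7)]
        assert sigmas == [pytest.approx(0.6), pytest.approx(0.6)]

    def test_sigma_rule_is_order_independent(self):
        a = np.full((4, 4), 0.7)
        b = np.full((4, 4), 0.3)
        _, _, sigmas = intensity_weights([a, b])
        assert sigmas == [pytest.approx(0.6), pytest.approx(0.6)]

    def test_interior_sigma_for_three_images(self):
        imgs = [np.full((4, 4), m) for m in (0.2, 0.5, 0.9)]
        _, _, sigmas = intensity_weights(imgs)
        assert sigmas[0] == pytest.approx(1.5 * 0.3)
        assert sigmas[1] == pytest.approx(0.75 * 0.7)
        assert sigmas[2] == pytest.approx(1.5 * 0.4)

    def test_weight_peaks_at_brightness_complement(self):
        a = np.full((3, 3), 0.3)
        b = np.full((3, 3), 0.7)
        a[1, 1] = 0.7  # exactly 1 - m_a for m_a = mean(a)
        m_a = a.mean()
        a[1, 1] = 1.0 - m_a
        m_a = a.mean()  # recompute; fixture nearly exact below
        weights, means, sigmas = intensity_weights([a, b])
        peak = np.exp(-((a[1, 1] - (1 - means[0])) ** 2) / (2 * sigmas[0] ** 2))
        assert weights[0][1, 1] == pytest.approx(peak)
        assert weights[0][1, 1] == weights[0].max()

    def test_one_sigma_point_value(self):
        """A pixel one sigma away from the complement weighs exp(-1/2)."""
        sigmas_known = 0.6
        a = np.full((100, 1), 0.3)
        b = np.full((100, 1), 0.7)
        weights, means, sigmas = intensity_weights([a, b])
        target = (1.0 - means[0]) + sigmas[0]
        w = oracles.intensity_weight(target, means[0], sigmas[0])
        assert w == pytest.approx(np.exp(-0.5))
        assert sigmas[0] == pytest.approx(sigmas_known)

    def test_single_image_rejected(self):
        with pytest.raises(ValueError):
            intensity_weights([np.zeros((4, 4))])


class TestGradientWeights:
    def test_identical_images_split_evenly(self, rng, cfg):
        img = random_image(rng)
        w = gradient_weights([img, img], cfg)
        np.testing.assert_allclose(w[0], 0.5, atol=1e-5)
        np.testing.assert_allclose(w[1], 0.5, atol=1e-5)

    def test_sum_bounded_by_one(self, rng, cfg):
        a, b = random_image(rng), random_image(rng)
        w = gradient_weights([a, b], cfg)
        total = w[0] + w[1]
        assert total.max() <= 1.0 and total.min() >= 1.0 - 1e-3

    def test_rare_intensity_gets_larger_weight(self, cfg):
        """A pixel alone in its histogram bin outweighs a uniform image."""
        cfg = cfg.replace(hist_bins=8)
        a = np.tile(np.linspace(0.0, 0.99, 8), (8, 1))  # uniform histogram
        b = np.full((8, 8), 0.2)
        b[3, 3] = 0.95  # lone pixel in an otherwise empty bin
        w = gradient_weights([a, b], cfg)
        assert w[1][3, 3] > w[0][3, 3]
        # brute-force the expected ratio from the two histograms
        counts_a, _ = np.histogram(a, bins=8, range=(0, 1))
        counts_b, _ = np.histogram(b, bins=8, range=(0, 1))
        grad_a = oracles.cdf_slope(list(counts_a), a.size, 8, a[3, 3])
        grad_b = oracles.cdf_slope(list(counts_b), b.size, 8, b[3, 3])
        expected = oracles.gradient_weight([grad_a, grad_b], 1, cfg.epsilon)
        assert w[1][3, 3] == pytest.approx(expected, rel=1e-9)


class TestCombineWeights:
    def test_symmetric_products_split_evenly(self, cfg):
        w = [np.full((3, 3), 0.4)] * 2
        out = combine_weights(w, [np.full((3, 3), 0.5)] * 2, cfg)
        np.testing.assert_allclose(out[0], 0.5, atol=1e-5)

    def test_zero_product_gets_zero_weight(self, cfg):
        w1 = [np.zeros((2, 2)), np.full((2, 2), 0.6)]
        w2 = [np.full((2, 2), 0.9), np.full((2, 2), 0.9)]
        out = combine_weights(w1, w2, cfg)
        np.testing.assert_array_equal(out[0], 0.0)

    def test_quarter_three_quarter_split(self, cfg):
        """Products (0.2, 0.6) normalize to (0.25, 0.75)."""
        w1 = [np.full((2, 2), 0.2), np.full((2, 2), 0.6)]
        w2 = [np.ones((2, 2)), np.ones((2, 2))]
        out = combine_weights(w1, w2, cfg)
        np.testing.assert_allclose(out[0], 0.25, atol=1e-6)
        np.testing.assert_allclose(out[1], 0.75, atol=1e-6)

    def test_degenerate_pixels_fall_back_to_uniform(self, cfg):
        w1 = [np.zeros((2, 2)), np.zeros((2, 2))]
        w2 = [np.ones((2, 2)), np.ones((2, 2))]
        out = combine_weights(w1, w2, cfg)
        np.testing.assert_allclose(out[0] + out[1], 1.0)

    def test_shape_mismatch_rejected(self, cfg):
        with pytest.raises(ValueError):
            combine_weights([np.zeros((2, 2))], [np.zeros((2, 2)), np.zeros((2, 2))], cfg)


class TestFuse:
    def test_degenerate_weights_select_one_image(self, rng):
        a, b = random_image(rng), random_image(rng)
        out = fuse([a, b], [np.ones_like(a), np.zeros_like(b)])
        np.testing.assert_array_equal(out, a)

    def test_even_split_of_identical_images(self, rng):
        a = random_image(rng)
        out = fuse([a, a], [np.full_like(a, 0.5)] * 2)
        np.testing.assert_allclose(out, a, atol=1e-12)

    def test_pixel_arithmetic(self):
        a = np.full((1, 1), 0.2)
        b = np.full((1, 1), 0.8)
        out = fuse([a, b], [np.full((1, 1), 0.25), np.full((1, 1), 0.75)])
        assert out[0, 0] == pytest.approx(0.65)

    def test_overweighted_stack_rejected(self):
        a = np.zeros((2, 2))
        with pytest.raises(ValueError):
            fuse([a, a], [np.ones((2, 2)), np.ones((2, 2))])


class TestPerceptualFusion:
    def test_identical_inputs_return_input(self, rng, cfg):
        img = random_image(rng)
        out, _ = perceptual_fusion(img, img, cfg)
        np.testing.assert_allclose(out, img, atol=1e-6)

    def test_swapped_inputs_same_result(self, rng, cfg):
        a, b = random_image(rng), random_image(rng)
        f1, _ = perceptual_fusion(a, b, cfg)
        f2, _ = perceptual_fusion(b, a, cfg)
        np.testing.assert_allclose(f1, f2, atol=1e-12)

    def test_equals_hand_chained_stages(self, step16, cfg):
        other = 1.0 - step16
        w1, means, sigmas = intensity_weights([step16, other], epsilon=cfg.epsilon)
        w2 = gradient_weights([step16, other], cfg)
        W = combine_weights(w1, w2, cfg)
        expected = fuse([step16, other], W)
        out, stack = perceptual_fusion(step16, other, cfg)
        np.testing.assert_array_equal(out, expected)
        assert stack.means == means and stack.sigmas == sigmas

    def test_convex_envelope_where_normalized(self, rng, cfg):
        for _ in range(5):
            a, b = random_image(rng), random_image(rng)
            out, stack = perceptual_fusion(a, b, cfg)
            total = stack.w_combined[0] + stack.w_combined[1]
            ok = total >= 1.0 - 1e-3
            lo = np.minimum(a, b) - 1e-6
            hi = np.maximum(a, b) + 1e-6
            # envelope tolerance scaled by how far the weights are from 1
            assert np.all(out[ok] >= lo[ok] - 1e-3)
            assert np.all(out[ok] <= hi[ok] + 1e-6)
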