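"""Preprocessing chain: white-out, resize, affine/gamma transforms,
per-channel standardization, and their composition."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chromotype import (
    DegenerateChannelError,
    PreprocessConfig,
    contrast_brightness,
    gamma_correct,
    preprocess_pipeline,
    resize_image,
    standardize_channels,
    whiteout,
)
from test_synthetic import count_dark_bodies


def scalar_affine(x, alpha=3.0, beta=80.0):
    return min(max(alpha * x + beta, 0.0), 255.0)


def scalar_gamma(x, gamma=3.0):
    return (x / 255.0) ** gamma * 255.0


class TestWhiteout:
    def test_all_false_mask_is_identity(self, small_images):
        im = small_images[0]
        out = whiteout(im, np.zeros(im.pixels.shape[:2], dtype=bool))
        assert np.array_equal(out, im.pixels.astype(float))

    def test_all_true_mask_gives_uniform_white(self, small_images):
        im = small_images[0]
        out = whiteout(im, np.ones(im.pixels.shape[:2], dtype=bool))
        assert (out == 255.0).all()

    def test_shape_mismatch_rejected(self, small_images):
        with pytest.raises(ValueError, match="mask shape"):
            whiteout(small_images[0], np.zeros((10, 10), dtype=bool))

    def test_masking_fragment_leaves_single_main_body(self, default_config):
        from dataclasses import replace
        from chromotype import generate_chromosome

        cfg = replace(default_config, fragment_probability=1.0)
        im = generate_chromosome("A", cfg, rng=5)
        assert count_dark_bodies(im.pixels) >= 2  # fragment photobombs
        cleaned = whiteout(im, im.geometry.fragment_mask)
        assert count_dark_bodies(cleaned.astype(np.uint8)) == 1


class TestResize:
    def test_same_size_is_identity(self, small_images):
        im = small_images[0]
        out = resize_image(im, 224, order=0)
        assert np.array_equal(out, im.pixels.astype(float))

    def test_constant_image_stays_constant(self):
        gray = np.full((100, 60, 3), 100.0)
        out = resize_image(gray, 224)
        assert np.allclose(out, 100.0)

    def test_downscaled_checkerboard_preserves_mean(self):
        board = np.indices((448, 448)).sum(axis=0) % 2 * 255.0
        img = np.repeat(board[:, :, None], 3, axis=2)
        out = resize_image(img, 224)
        assert abs(out.mean() - img.mean()) < 1.0

    def test_zero_dimension_rejected(self):
        with pytest.raises(ValueError, match="zero dimension"):
            resize_image(np.zeros((0, 10, 3)), 224)


class TestAffineAndGamma:
    def test_affine_matches_scalar_oracle_exhaustively(self):
        # every 8-bit value, with the published parameter set
        values = np.arange(256, dtype=float)
        img = np.repeat(values[None, :, None], 3, axis=2)
        out = contrast_brightness(img, 3.0, 80.0)
        expected = np.array([scalar_affine(v) for v in values])
        assert np.array_equal(out[0, :, 0], expected)

    def test_gamma_matches_scalar_oracle_exhaustively(self):
        values = np.arange(256, dtype=float)
        img = np.repeat(values[None, :, None], 3, axis=2)
        out = gamma_correct(img, 3.0)
        expected = np.array([scalar_gamma(v) for v in values])
        assert np.allclose(out[0, :, 0], expected, atol=1e-9)

    def test_affine_identity_parameters(self, small_images):
        im = small_images[0]
        assert np.array_equal(contrast_brightness(im, 1.0, 0.0), im.pixels.astype(float))

    def test_affine_clips_at_255(self):
        assert contrast_brightness(np.full((2, 2, 3), 100.0), 3.0, 80.0).max() == 255.0

    def test_gamma_fixes_endpoints_and_identity(self, small_images):
        for g in (0.5, 1.0, 3.0):
            img = np.array([[[0.0] * 3, [255.0] * 3]])
            out = gamma_correct(img, g)
            assert out[0, 0, 0] == 0.0 and out[0, 1, 0] == 255.0
        im = small_images[0]
        assert np.allclose(gamma_correct(im, 1.0), im.pixels.astype(float))

    def test_gamma_midpoint_value(self):
        out = gamma_correct(np.full((1, 1, 3), 128.0), 3.0)
        assert abs(out[0, 0, 0] - (128 / 255) ** 3 * 255) < 1e-9

    @settings(deadline=None, max_examples=25)
    @given(gamma=st.floats(0.2, 5.0))
    def test_gamma_is_monotone(self, gamma):
        values = np.linspace(0, 255, 64)
        img = np.repeat(values[None, :, None], 3, axis=2)
        out = gamma_correct(img, gamma)[0, :, 0]
        assert (np.diff(out) >= 0).all()

    def test_nonpositive_parameters_rejected(self):
        img = np.zeros((2, 2, 3))
        with pytest.raises(ValueError):
            contrast_brightness(img, 0.0, 1.0)
        with pytest.raises(ValueError):
            gamma_correct(img, 0.0)


class TestStandardize:
    def test_targets_hit_on_every_synthetic_image(self, small_images):
        for im in small_images:
            out = standardize_channels(im, 64.0, 16.0)
            for c in range(3):
                assert abs(out[:, :, c].mean() - 64.0) < 0.5
                assert abs(out[:, :, c].std() - 16.0) < 0.5

    def test_already_standardized_image_unchanged(self):
        rng = np.random.default_rng(0)
        img = rng.normal(size=(32, 32, 3))
        img = (img - img.mean(axis=(0, 1))) / img.std(axis=(0, 1)) * 16.0 + 64.0
        out = standardize_channels(img, 64.0, 16.0)
        assert np.allclose(out, img, atol=1e-9)

    def test_constant_channel_raises_named_error(self):
        img = np.zeros((8, 8, 3))
        img[:, :, 0] = np.linspace(0, 255, 64).reshape(8, 8)
        img[:, :, 2] = img[:, :, 0]
        with pytest.raises(DegenerateChannelError, match="channel G"):
            standardize_channels(img)


class TestPipeline:
    def test_deterministic_and_correct_shape(self, small_images):
        im = small_images[0]
        cfg = PreprocessConfig()
        a = preprocess_pipeline(im, config=cfg)
        b = preprocess_pipeline(im, config=cfg)
        assert a.shape == (224, 224, 3)
        assert np.array_equal(a, b)

    def test_output_statistics_match_normalization_targets(self, small_images):
        out = preprocess_pipeline(small_images[3], config=PreprocessConfig())
        for c in range(3):
            assert abs(out[:, :, c].mean() - 64.0) < 0.5
            assert abs(out[:, :, c].std() - 16.0) < 0.5

    def test_fully_masked_image_degenerates(self, small_images):
        im = small_images[0]
        mask = np.ones(im.pixels.shape[:2], dtype=bool)
        with pytest.raises(DegenerateChannelError):
            preprocess_pipeline(im, mask=mask)

    def test_shape_idempotence(self, small_images):
        cfg = PreprocessConfig()
        once = preprocess_pipeline(small_images[0], config=cfg)
        twice = preprocess_pipeline(once, config=cfg)
        assert twice.shape == (224, 224, 3)

    def test_stage_order_is_permutable(self, small_images):
        cfg = PreprocessConfig(
            stage_order=(
                "resize",
                "whiteout",
                "contrast_brightness",
                "gamma",
                "standardize",
            )
        )
        out = preprocess_pipeline(small_images[0], config=cfg)
        assert out.shape == (224, 224, 3)

    def test_grayscale_input_replicated_to_three_channels(self):
        rng = np.random.default_rng(1)
        gray = rng.integers(0, 200, size=(64, 64)).astype(np.uint8)
        out = preprocess_pipeline(gray, config=PreprocessConfig())
        assert out.shape == (224, 224, 3)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            PreprocessConfig(alpha=-1.0)
        with pytest.raises(ValueError):
            PreprocessConfig(output_size=4)
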