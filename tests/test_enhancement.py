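"""CLAHE, bilateral filtering, gain/bias and the two-stage pipeline."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from naive_oracles import naive_bilateral, naive_gaussian_blur
from retilume import colorspace
from retilume.enhancement import (
    BilateralParams,
    BrightnessContrastParams,
    ClaheParams,
    EnhanceConfig,
    apply_gain_bias,
    bilateral_filter,
    clahe,
    compute_gain_bias,
    enhance_image,
    stage1_enhance,
    stage2_enhance,
)
from retilume.metrics import shannon_entropy
from retilume.synthfundus import generate, spec_for_preset


class TestClahe:
    def test_output_in_range_and_same_shape(self, rng):
        plane = rng.integers(0, 256, size=(57, 91), dtype=np.uint8)
        out = clahe(plane)
        assert out.shape == plane.shape and out.dtype == np.uint8

    @pytest.mark.parametrize("value", [0, 50, 128, 255])
    def test_constant_plane_stays_constant_near_identity(self, value):
        # with clipped+redistributed histograms the equalization mapping is
        # near identity; the exact deviation bound for clip c, b bins is
        # ceil(255·c/b)+1 gray levels (the clipped spike shifts the cdf)
        params = ClaheParams(clip_limit=2.0, bins=256)
        out = clahe(np.full((64, 64), value, np.uint8), params)
        assert len(np.unique(out)) == 1
        bound = math.ceil(255 * params.clip_limit / params.bins) + 1
        assert abs(int(out[0, 0]) - value) <= bound

    def test_single_tile_unclipped_equals_global_equalization(self):
        # half 0 / half 255 with an effectively infinite clip: the global
        # cdf maps the two levels to ≈127.5 and 255
        plane = np.zeros((64, 64), np.uint8)
        plane[32:] = 255
        out = clahe(plane, ClaheParams(clip_limit=1e9, tile_grid=(1, 1)))
        low, high = np.unique(out)
        assert abs(int(low) - 127.5) <= 1.0
        assert high == 255

    def test_plane_smaller_than_tile_grid_rejected(self):
        with pytest.raises(ValueError):
            clahe(np.zeros((4, 4), np.uint8), ClaheParams(tile_grid=(8, 8)))

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            ClaheParams(clip_limit=0.0)
        with pytest.raises(ValueError):
            ClaheParams(tile_grid=(0, 8))
        with pytest.raises(ValueError):
            ClaheParams(bins=1)

    def test_raises_on_non_2d_input(self):
        with pytest.raises(ValueError):
            clahe(np.zeros((8, 8, 3), np.uint8))


class TestBilateralFilter:
    def test_matches_double_loop_oracle_on_small_images(self, rng):
        for radius in (1, 2):
            params = BilateralParams(sigma_d=2.0, sigma_r=30.0, radius=radius)
            for _ in range(10):
                plane = rng.uniform(0, 255, size=(4, 4))
                ours = bilateral_filter(plane, params)
                oracle = naive_bilateral(plane, 2.0, 30.0, radius)
                assert np.abs(ours - oracle).max() < 1e-9

    def test_huge_sigma_r_reduces_to_gaussian_smoothing(self, rng):
        plane = rng.uniform(0, 255, size=(16, 16))
        params = BilateralParams(sigma_d=2.0, sigma_r=1e6, radius=3)
        ours = bilateral_filter(plane, params)
        gaussian = naive_gaussian_blur(plane, 2.0, 3)
        assert np.abs(ours - gaussian).max() < 1e-3

    def test_constant_image_unchanged(self):
        img = np.full((16, 16, 3), 93, np.uint8)
        assert np.array_equal(bilateral_filter(img), img)

    def test_uint8_input_gives_uint8_output(self, random_rgb):
        out = bilateral_filter(random_rgb)
        assert out.dtype == np.uint8 and out.shape == random_rgb.shape

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            BilateralParams(sigma_d=0.0)
        with pytest.raises(ValueError):
            BilateralParams(radius=0)


class TestGainBias:
    def test_full_range_image_yields_identity(self):
        img = np.arange(256, dtype=np.uint8)[:, None, None] * np.ones((1, 1, 3), np.uint8)
        params = compute_gain_bias(img, clip_percent=0.0)
        assert params.alpha == pytest.approx(1.0)
        assert params.beta == pytest.approx(0.0)

    def test_narrow_range_stretch_hand_value(self, rng):
        values = rng.integers(50, 101, size=(32, 32))
        values.flat[0], values.flat[1] = 50, 100  # pin the extremes
        img = np.stack([values] * 3, axis=-1).astype(np.uint8)
        params = compute_gain_bias(img, clip_percent=0.0)
        assert params.alpha == pytest.approx(255.0 / 50.0)
        assert params.beta == pytest.approx(-50.0 * 255.0 / 50.0)
        out = apply_gain_bias(img, params)
        assert out.min() == 0 and out.max() == 255

    def test_constant_image_falls_back_to_identity(self):
        params = compute_gain_bias(np.full((8, 8, 3), 77, np.uint8))
        assert (params.alpha, params.beta) == (1.0, 0.0)

    def test_apply_identity_and_clamping(self):
        img = np.array([[[200, 10, 128]]], np.uint8)
        assert np.array_equal(apply_gain_bias(img, BrightnessContrastParams(1.0, 0.0)), img)
        clamped = apply_gain_bias(img, BrightnessContrastParams(2.0, -100.0))
        assert tuple(clamped[0, 0]) == (255, 0, 156)

    @settings(max_examples=50, derandomize=True)
    @given(
        st.floats(0.1, 5.0),
        st.floats(-200.0, 200.0),
        st.integers(0, 255),
        st.integers(0, 255),
    )
    def test_mapping_is_monotone(self, alpha, beta, v1, v2):
        lo, hi = sorted((v1, v2))
        params = BrightnessContrastParams(alpha, beta)
        a = apply_gain_bias(np.full((1, 1, 3), lo, np.uint8), params)
        b = apply_gain_bias(np.full((1, 1, 3), hi, np.uint8), params)
        assert np.all(a <= b)

    def test_non_positive_gain_rejected(self):
        with pytest.raises(ValueError):
            BrightnessContrastParams(0.0, 0.0)


def _stage1_replay(image, selected_idx):
    """Replay the Stage-1 chroma edit out of public primitives: modify only
    the selected Lab plane, leave the other two bit-identical, convert back."""
    from retilume.dominance import crop_square_retina

    cropped = crop_square_retina(image).image
    out, dom = stage1_enhance(cropped)
    before = colorspace.rgb_to_lab(cropped)
    after = colorspace.rgb_to_lab(out)

    lab_mod = before.copy()
    embedded = colorspace.lab_chroma_to_uint8(before[..., selected_idx])
    lab_mod[..., selected_idx] = colorspace.uint8_to_lab_chroma(clahe(embedded))
    recon = colorspace.lab_to_rgb(lab_mod)
    linear = colorspace.lab_to_xyz(lab_mod) @ colorspace.XYZ_TO_RGB_MATRIX.T
    in_gamut = np.all((linear > -1e-9) & (linear < 1 + 1e-9), axis=-1)
    return out, recon, before, after, in_gamut, dom


class TestStage1:
    def test_red_dominant_phantom_modifies_only_a_star(self, red_phantom):
        image, _ = red_phantom
        out, recon, before, after, in_gamut, dom = _stage1_replay(image, selected_idx=1)
        assert dom.selected_channel == "a_star"
        # strongest form of the untouched-plane contract: the output is
        # bit-identical to a reconstruction in which only a* was edited
        assert np.array_equal(out, recon)
        # perceptual corroboration where no gamut clamp fired and away from
        # black (near black one RGB quantum moves Lab by several units)
        mask = in_gamut & (before[..., 0] >= 10)
        assert mask.mean() > 0.5
        assert np.abs(after[..., 0] - before[..., 0])[mask].max() < 2.0
        assert np.median(np.abs(after[..., 2] - before[..., 2])[mask]) < 0.5

    def test_pale_phantom_modifies_only_b_star(self, pale_phantom):
        image, _ = pale_phantom
        out, recon, before, after, in_gamut, dom = _stage1_replay(image, selected_idx=2)
        assert dom.selected_channel == "b_star"
        assert np.array_equal(out, recon)
        mask = in_gamut & (before[..., 0] >= 10)
        assert mask.mean() > 0.5
        assert np.abs(after[..., 0] - before[..., 0])[mask].max() < 2.0
        assert np.median(np.abs(after[..., 1] - before[..., 1])[mask]) < 0.5


class TestStage2:
    def test_red_blue_untouched_by_green_clahe_step(self, red_phantom):
        image, _ = red_phantom
        stage1, _ = stage1_enhance(image)
        _, inter = stage2_enhance(stage1, return_intermediates=True)
        green_step = inter["stage2_green"]
        assert np.array_equal(green_step[..., 0], stage1[..., 0])
        assert np.array_equal(green_step[..., 2], stage1[..., 2])
        assert not np.array_equal(green_step[..., 1], stage1[..., 1])

    def test_constant_gray_input_stays_constant(self):
        img = np.full((64, 64, 3), 120, np.uint8)
        out = stage2_enhance(img)
        assert out.shape == img.shape and out.dtype == np.uint8
        for c in range(3):
            assert len(np.unique(out[..., c])) == 1

    def test_output_shape_and_dtype_match_input(self, red_phantom):
        image, _ = red_phantom
        stage1, _ = stage1_enhance(image)
        out = stage2_enhance(stage1)
        assert out.shape == stage1.shape and out.dtype == np.uint8


class TestFullPipeline:
    def test_same_input_and_config_is_bit_identical(self, red_phantom):
        image, _ = red_phantom
        a = enhance_image(image)
        b = enhance_image(image)
        assert np.array_equal(a.image, b.image)
        assert a.dominance == b.dominance

    def test_pale_phantom_records_b_star_end_to_end(self, pale_phantom):
        image, _ = pale_phantom
        result = enhance_image(image)
        assert result.dominance.selected_channel == "b_star"
        assert result.image.min() >= 0 and result.image.max() <= 255

    def test_entropy_increases_on_low_contrast_phantoms(self):
        increased = 0
        for seed in range(10):
            image, _ = generate(spec_for_preset("red", seed=seed))
            result = enhance_image(image)
            e_in = shannon_entropy(np.round(result.crop.image.mean(axis=2)))
            e_out = shannon_entropy(np.round(result.image.mean(axis=2)))
            increased += e_out > e_in
        assert increased >= 9

    def test_intermediates_retained_on_request(self, red_phantom):
        image, _ = red_phantom
        result = enhance_image(image, EnhanceConfig(keep_intermediates=True))
        assert result.intermediates is not None
        assert set(result.intermediates) == {
            "cropped",
            "stage1",
            "stage2_green",
            "stage2_bilateral",
            "final",
        }
        assert np.array_equal(result.intermediates["final"], result.image)

    def test_all_dark_image_raises_no_retina(self):
        from retilume.dominance import RetinaNotFoundError

        with pytest.raises(RetinaNotFoundError):
            enhance_image(np.zeros((128, 128, 3), np.uint8))
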