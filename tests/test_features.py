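"""Color, LBP and Gabor feature extraction on analytically known images."""

import numpy as np
import pytest
from skimage.color import rgb2lab

from sanqigrade import (FeatureConfig, GaborConfig, MaskConfig, SliceImage,
                        color_moments, convert_color_planes, extract_features,
                        foreground_mask, gabor_energy, lbp_histogram)
from sanqigrade.features import (_count_transitions, grayscale_plane, lbp_codes,
                                 uniform_pattern_table)


def single_pixel_image(r, g, b):
    return SliceImage(pixels=np.full((3, 3, 3), 0.0)
                      + np.array([r, g, b])[None, None, :])


class TestColorPlanes:
    @pytest.mark.parametrize("rgb,expected_h", [
        ((1.0, 0.0, 0.0), 0.0),     # pure red: arccos(1) = 0
        ((1.0, 1.0, 0.0), 60.0),    # yellow: arccos(0.5)
        ((0.0, 1.0, 0.0), 120.0),
        ((0.0, 0.0, 1.0), 240.0),   # B > G branch: 360 - 120
    ])
    def test_hue_arccos_form(self, rgb, expected_h):
        planes = convert_color_planes(single_pixel_image(*rgb))
        assert planes.H[1, 1] == pytest.approx(expected_h, abs=1e-9)

    @pytest.mark.parametrize("g", [0.0, 0.3, 1.0])
    def test_gray_pixels_are_achromatic(self, g):
        planes = convert_color_planes(single_pixel_image(g, g, g))
        assert planes.H[1, 1] == 0.0
        assert planes.S[1, 1] == 0.0
        assert abs(planes.a[1, 1]) < 1e-6 and abs(planes.b[1, 1]) < 1e-6

    def test_srgb_red_lab_coordinates(self):
        # independent reference: sRGB red -> (a, b) ~ (80.1, 67.2) under D65
        planes = convert_color_planes(single_pixel_image(1.0, 0.0, 0.0))
        assert planes.a[1, 1] == pytest.approx(80.1, abs=0.2)
        assert planes.b[1, 1] == pytest.approx(67.2, abs=0.2)

    def test_lab_matches_reference_implementation(self, random_image):
        # cross-check against scikit-image; small offsets remain because the
        # reference normalizes with tabulated D65 rather than the matrix white
        planes = convert_color_planes(random_image)
        lab = rgb2lab(random_image.pixels)
        np.testing.assert_allclose(planes.a, lab[:, :, 1], atol=0.05)
        np.testing.assert_allclose(planes.b, lab[:, :, 2], atol=0.05)

    def test_hue_in_range_and_saturation_unit_interval(self, random_image):
        planes = convert_color_planes(random_image)
        assert np.all((planes.H >= 0) & (planes.H < 360))
        assert np.all((planes.S >= -1e-12) & (planes.S <= 1 + 1e-12))

    def test_rejects_nonfinite_pixels(self):
        with pytest.raises(ValueError):
            SliceImage(pixels=np.full((4, 4, 3), np.nan))


class TestColorMoments:
    def test_constant_image_has_zero_sigmas(self, constant_image):
        moments = color_moments(constant_image)
        assert len(moments) == 14
        sigmas = moments[1::2]
        np.testing.assert_allclose(sigmas, 0.0, atol=1e-12)

    def test_hand_computed_mean_and_sd(self):
        # R channel {0.0, 0.2, 0.4, 0.6} over a 2x2 block inside a 3x3 image
        pixels = np.zeros((3, 3, 3))
        mask = np.zeros((3, 3), dtype=bool)
        mask[:2, :2] = True
        pixels[:2, :2, 0] = np.array([[0.0, 0.2], [0.4, 0.6]])
        img = SliceImage(pixels=pixels, mask=mask)
        moments = color_moments(img)
        assert moments[0] == pytest.approx(0.3)
        assert moments[1] == pytest.approx(np.sqrt(0.05), abs=1e-9)  # 1/N form

    def test_rotation_invariance(self, random_image):
        rotated = SliceImage(pixels=np.rot90(random_image.pixels).copy())
        np.testing.assert_allclose(color_moments(random_image),
                                   color_moments(rotated), atol=1e-9)

    def test_empty_foreground_rejected(self, random_image):
        img = SliceImage(pixels=random_image.pixels,
                         mask=np.zeros(random_image.shape, dtype=bool))
        with pytest.raises(ValueError):
            color_moments(img)


class TestForegroundMask:
    def test_flat_image_gives_full_mask(self, constant_image):
        assert foreground_mask(constant_image).all()

    def test_disc_recovered_within_two_percent(self):
        yy, xx = np.mgrid[0:64, 0:64]
        disc = (yy - 32) ** 2 + (xx - 32) ** 2 <= 20**2
        pixels = np.where(disc[..., None], 0.9, 0.05) * np.ones((64, 64, 3))
        mask = foreground_mask(SliceImage(pixels=pixels))
        assert abs(mask.sum() - disc.sum()) / disc.sum() < 0.02

    def test_disabled_masking_returns_all_true(self, random_image):
        mask = foreground_mask(random_image, MaskConfig(enabled=False))
        assert mask.all()


class TestUniformLbp:
    def test_exhaustive_u2_enumeration(self):
        # independent brute-force count of uniform 8-bit patterns
        uniform = [c for c in range(256) if _count_transitions(c) <= 2]
        assert len(uniform) == 58
        table = uniform_pattern_table(8)
        assert table.max() == 58  # one shared catch-all bin
        singles = np.bincount(table, minlength=59)
        assert np.all(singles[:58] == 1) and singles[58] == 256 - 58

    def test_hand_evaluated_window_code(self):
        # neighbors clockwise from top-left are 1,2,3,4,6,7,8,9 around center 5
        patch = np.array([[1, 2, 3],
                          [9, 5, 4],
                          [8, 7, 6]], dtype=np.uint8)
        code = lbp_codes(patch)[0, 0]
        bits = [(code >> p) & 1 for p in range(8)]
        assert bits == [0, 0, 0, 0, 1, 1, 1, 1]

    def test_codes_match_per_pixel_loop(self, rng):
        gray = rng.integers(0, 256, (8, 8)).astype(np.uint8)
        codes = lbp_codes(gray)
        offsets = [(-1, -1), (-1, 0), (-1, 1), (0, 1),
                   (1, 1), (1, 0), (1, -1), (0, -1)]
        for y in range(1, 7):
            for x in range(1, 7):
                expected = sum(
                    (int(gray[y + dy, x + dx]) >= int(gray[y, x])) << p
                    for p, (dy, dx) in enumerate(offsets))
                assert codes[y - 1, x - 1] == expected

    def test_constant_image_ties_score_one(self, constant_image):
        hist = lbp_histogram(constant_image)
        assert len(hist) == 59
        full_code_bin = uniform_pattern_table(8)[255]
        assert hist[full_code_bin] == pytest.approx(1.0)

    def test_histogram_normalized(self, random_image):
        hist = lbp_histogram(random_image)
        assert hist.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(hist >= 0)

    def test_background_touching_windows_dropped(self, rng):
        pixels = rng.random((10, 10, 3))
        mask = np.zeros((10, 10), dtype=bool)
        mask[:5, :] = True  # interior-foreground windows exist only in rows 1-3
        img = SliceImage(pixels=pixels, mask=mask)
        hist = lbp_histogram(img)
        assert hist.sum() == pytest.approx(1.0)
        with pytest.raises(ValueError):
            # a 1-pixel-thick foreground has no fully-interior window
            thin = np.zeros((10, 10), dtype=bool)
            thin[4, :] = True
            lbp_histogram(SliceImage(pixels=pixels, mask=thin))


class TestGaborEnergy:
    def test_zero_image_gives_zero_energies(self):
        img = SliceImage(pixels=np.zeros((40, 40, 3)))
        energies = gabor_energy(img)
        assert len(energies) == 40
        np.testing.assert_array_equal(energies, 0.0)

    def test_orientation_selectivity_on_grating(self):
        cfg = GaborConfig()
        scale = 2
        freq = cfg.f_max / np.sqrt(2.0) ** scale
        x = np.arange(64)
        grating = 0.5 + 0.4 * np.sin(2 * np.pi * freq * x)[None, :]
        pixels = np.repeat(grating[..., None], 3, axis=2) * np.ones((64, 64, 3))
        energies = gabor_energy(SliceImage(pixels=pixels), cfg).reshape(5, 8)
        # the grating varies along x: the theta = 0 filter must respond most
        assert np.argmax(energies[scale]) == 0

    def test_intensity_scaling_homogeneity(self, rng):
        pixels = rng.random((40, 40, 3)) * 0.5 + 0.25
        img = SliceImage(pixels=pixels)
        half = SliceImage(pixels=pixels * 0.5)
        e1 = gabor_energy(img)
        e2 = gabor_energy(half)
        # 8-bit grayscale quantization makes the scaling only approximate
        np.testing.assert_allclose(e2, 0.5 * e1, rtol=0.15, atol=5e-4)


class TestFusedVector:
    def test_length_and_segment_order(self, random_image):
        vec = extract_features(random_image)
        assert len(vec.values) == 113
        assert vec.names[0].startswith("color_")
        assert vec.names[14].startswith("lbp_")
        assert vec.names[73].startswith("gabor_")
        assert len(set(vec.names)) == 113

    def test_bitwise_determinism(self, random_image):
        a = extract_features(random_image).values
        b = extract_features(random_image).values
        np.testing.assert_array_equal(a, b)

    def test_constant_image_composition(self, constant_image):
        vec = extract_features(constant_image).values
        np.testing.assert_allclose(vec[1:14:2], 0.0, atol=1e-12)  # sigmas
        lbp = vec[14:73]
        assert lbp.max() == pytest.approx(1.0)  # all mass in the tie-rule bin
        np.testing.assert_array_equal(vec[73:], 0.0)  # DC-free Gabor bank

    def test_masking_config_changes_output_deterministically(self, rng):
        pixels = np.full((40, 40, 3), 0.05)
        pixels[10:30, 10:30] = rng.random((20, 20, 3)) * 0.5 + 0.4
        img = SliceImage(pixels=pixels)
        masked = extract_features(img)
        unmasked = extract_features(
            img, FeatureConfig(mask=MaskConfig(enabled=False)))
        assert not np.allclose(masked.values, unmasked.values)
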