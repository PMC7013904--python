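import numpy as np
import pytest

from conftest import brute_force_closing
from thermocrop import (
    CanopyMask,
    FIXTURE_PLANCK,
    NoCanopyError,
    TemperatureMap,
    frame_to_temperature,
    grvi,
    mean_masked_temperature,
    morphological_refine,
    remove_small_regions,
    threshold_mask,
)


class TestGrvi:
    @pytest.mark.parametrize(
        "rgb, expected",
        [
            ((0, 255, 0), 1.0),          # pure green leaf extreme
            ((80, 80, 13), 0.0),         # gray: symmetric in R and G
            ((100, 120, 0), 20 / 220),   # direct arithmetic
            ((0, 0, 0), 0.0),            # black: sentinel for zero denominator
        ],
    )
    def test_pointwise_values(self, rgb, expected):
        img = np.tile(np.array(rgb, np.uint8), (4, 5, 1))
        assert grvi(img).values[0, 0] == pytest.approx(expected, abs=1e-12)

    def test_blue_channel_ignored(self):
        a = np.tile(np.array((100, 120, 0), np.uint8), (4, 5, 1))
        b = np.tile(np.array((100, 120, 250), np.uint8), (4, 5, 1))
        np.testing.assert_array_equal(grvi(a).values, grvi(b).values)


class TestThreshold:
    def test_gray_image_gives_empty_mask(self):
        img = np.full((10, 10, 3), 90, np.uint8)
        assert threshold_mask(grvi(img), 0.04).area == 0

    def test_comparison_is_inclusive_at_threshold(self):
        from thermocrop.segmentation import GrviMap

        gm = GrviMap(np.full((3, 3), 0.04))
        assert threshold_mask(gm, 0.04).area == 9

    def test_known_canopy_fraction_recovered_exactly(self, clean_scene):
        from thermocrop.registration import extract_overlap, scale_visible

        cfg = clean_scene.true_config()
        scaled = scale_visible(clean_scene.visible, cfg.registration.Sx, cfg.registration.Sy)
        mask = threshold_mask(grvi(extract_overlap(scaled, cfg.registration)), 0.04)
        np.testing.assert_array_equal(mask.M, clean_scene.mask_true.M)


class TestMorphology:
    def test_matches_brute_force_oracle_on_random_masks(self):
        rng = np.random.default_rng(2024)
        for _ in range(25):
            m = (rng.random((24, 32)) < 0.35).astype(np.uint8)
            got = morphological_refine(CanopyMask(m), 4).M
            np.testing.assert_array_equal(got, brute_force_closing(m, 4))

    def test_all_ones_mask_matches_oracle_border_convention(self):
        m = np.ones((24, 32), np.uint8)
        got = morphological_refine(CanopyMask(m), 4).M
        np.testing.assert_array_equal(got, brute_force_closing(m, 4))
        # interior is untouched; only the zero-padded border can erode
        assert got[4:-4, 4:-4].all()

    def test_small_interior_hole_is_filled(self):
        m = np.zeros((60, 60), np.uint8)
        m[5:55, 5:55] = 1
        m[25:27, 25:27] = 0
        got = morphological_refine(CanopyMask(m), 4).M
        assert got[25:27, 25:27].all()

    def test_empty_mask_stays_empty(self):
        got = morphological_refine(CanopyMask(np.zeros((20, 20), np.uint8)), 4)
        assert got.area == 0

    def test_oversized_kernel_rejected(self):
        with pytest.raises(ValueError):
            morphological_refine(CanopyMask(np.ones((3, 3), np.uint8)), 5)


class TestSmallRegionRemoval:
    def test_area_budget_computed_once_before_deletion(self):
        m = np.zeros((40, 40), np.uint8)
        m[2:12, 2:12] = 1  # 100 px
        m[30:31, 30:35] = 1  # 5 px < 0.1 * 105 = 10.5
        got = remove_small_regions(CanopyMask(m), 0.1)
        assert got.area == 100
        assert not got.M[30, 30]

    def test_single_component_always_survives(self):
        m = np.zeros((20, 20), np.uint8)
        m[3:5, 3:5] = 1
        got = remove_small_regions(CanopyMask(m), 0.1)
        np.testing.assert_array_equal(got.M, m)

    def test_two_equal_components_both_kept(self):
        m = np.zeros((20, 20), np.uint8)
        m[2:6, 2:6] = 1
        m[12:16, 12:16] = 1
        assert remove_small_regions(CanopyMask(m), 0.1).area == 32

    def test_diagonal_touch_counts_as_one_component(self):
        # 8-connectivity: diagonal leaf structures must not fragment
        m = np.zeros((10, 10), np.uint8)
        m[2:5, 2:5] = 1
        m[5, 5] = 1  # touches (4,4) diagonally only
        got = remove_small_regions(CanopyMask(m), 0.1)
        assert got.M[5, 5] == 1

    def test_output_foreground_subset_of_input(self):
        rng = np.random.default_rng(5)
        m = (rng.random((48, 64)) < 0.3).astype(np.uint8)
        got = remove_small_regions(CanopyMask(m), 0.1)
        assert not np.any(got.M & ~m)

    def test_empty_input_allowed(self):
        got = remove_small_regions(CanopyMask(np.zeros((8, 8), np.uint8)), 0.1)
        assert got.area == 0


class TestMaskedMean:
    def test_constant_map_returns_constant(self):
        tmap = TemperatureMap(np.full((240, 320), 300.0))
        m = np.zeros((240, 320), np.uint8)
        m[10:20, 10:20] = 1
        T, n = mean_masked_temperature(tmap, CanopyMask(m))
        assert (T, n) == (300.0, 100)

    def test_two_pixel_average(self):
        arr = np.full((4, 4), 310.0)
        arr[0, 0], arr[0, 1] = 299.0, 301.0
        m = np.zeros((4, 4), np.uint8)
        m[0, :2] = 1
        T, n = mean_masked_temperature(TemperatureMap(arr), CanopyMask(m))
        assert (T, n) == (300.0, 2)

    def test_empty_mask_is_a_distinct_error(self):
        tmap = TemperatureMap(np.full((4, 4), 300.0))
        with pytest.raises(NoCanopyError, match="no canopy detected"):
            mean_masked_temperature(tmap, CanopyMask(np.zeros((4, 4), np.uint8)))

    def test_scene_canopy_mean_recovered_within_sampling_error(self):
        from thermocrop import SceneSpec, generate_scene

        spec = SceneSpec(seed=3, T_canopy_sd=0.5, thermal_noise_sd=0.0, color_noise_sd=0.0)
        scene = generate_scene(spec)
        cfg = scene.true_config()
        tmap = frame_to_temperature(scene.thermal, cfg.radiometric, FIXTURE_PLANCK)
        T, n = mean_masked_temperature(tmap, scene.mask_true)
        tol = 3 * spec.T_canopy_sd / np.sqrt(n) + 0.01  # sampling + count quantization
        assert abs(T - spec.T_canopy_mean) < tol
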