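"""Image-level decomposition, box-whisker statistics, quiver export and
cross-method comparison."""
import numpy as np
import pytest

from muellerpol import (
    MaskReason,
    MuellerImage,
    PixelMask,
    azimuth_summary,
    boxwhisker_summary,
    compare_methods,
    decompose_image,
    generate_image,
    quiver_export,
    retarder_mueller,
    scenario_presets,
)
from muellerpol.maps import circular_median_deg, fold_angle_difference_deg
from muellerpol.simulate import LayerSpec, NoiseSpec, StackSpec


def _constant_scene(delta=18.0, theta=90.0, shape=(24, 24)):
    pixels = np.broadcast_to(retarder_mueller(delta, theta), shape + (4, 4)).copy()
    return MuellerImage(pixels)


class TestDecomposeImage:
    def test_constant_retarder_image_gives_constant_maps(self):
        dec = decompose_image(_constant_scene(), method="both")
        assert dec.mask.valid.all()
        np.testing.assert_allclose(dec.differential["Rt_deg"], 18.0, atol=1e-8)
        np.testing.assert_allclose(dec.lu_chipman["Rt_deg"], 18.0, atol=1e-8)
        np.testing.assert_allclose(dec.differential["theta_deg"], 90.0, atol=1e-8)

    def test_hole_pixels_are_flagged_below_noise_floor(self):
        layer = LayerSpec(10.0, 1.8, 90.0, hole_fraction=0.15, hole_radius_px=2)
        img, truth = generate_image(StackSpec([layer]), NoiseSpec(0.0, seed=2), (32, 32))
        dec = decompose_image(img, method="differential", noise_floor_deg=3.0)
        holes = truth["holes"]
        assert holes.any()
        assert np.all(dec.differential["Rt_deg"][holes] < 1e-6)
        assert np.all(dec.mask.reason[holes] == MaskReason.BELOW_NOISE_FLOOR)

    def test_both_methods_share_one_mask(self):
        stack, _ = scenario_presets("single")
        img, _ = generate_image(stack, NoiseSpec(seed=3), (16, 16))
        dec = decompose_image(img, method="both")
        assert dec.differential is not None and dec.lu_chipman is not None
        nan_d = np.isnan(dec.differential["Rt_deg"])
        nan_l = np.isnan(dec.lu_chipman["Rt_deg"])
        np.testing.assert_array_equal(nan_d, ~dec.mask.valid)
        np.testing.assert_array_equal(nan_l, ~dec.mask.valid)

    def test_determinism(self):
        stack, noise = scenario_presets("crossed45")
        img, _ = generate_image(stack, noise, (16, 16))
        d1 = decompose_image(img, method="both")
        d2 = decompose_image(img, method="both")
        np.testing.assert_array_equal(d1.differential["Rt_deg"], d2.differential["Rt_deg"])
        np.testing.assert_array_equal(d1.lu_chipman["alpha_t"], d2.lu_chipman["alpha_t"])

    def test_substrate_reference_is_factored_out(self):
        img = _constant_scene(30.0, 40.0, (8, 8))
        glass = 0.99 * np.eye(4)
        observed = MuellerImage(img.pixels @ glass)
        dec = decompose_image(observed, method="differential", substrate_ref=glass)
        np.testing.assert_allclose(dec.differential["Rt_deg"], 30.0, atol=1e-8)


class TestBoxWhisker:
    def test_constant_map(self):
        s = boxwhisker_summary(np.full((5, 5), 18.0), map_name="Rt")
        assert (s.median, s.q1, s.q3) == (18.0, 18.0, 18.0)
        assert s.n_outliers == 0
        assert s.n_valid == 25

    def test_hand_computed_outlier_rule(self):
        # {1,2,3,4,100}: linear-interpolation quartiles q1=2, q3=4, IQR=2,
        # fences [-1, 7] -> 100 is the only outlier, whiskers 1 and 4
        s = boxwhisker_summary(np.array([[1.0, 2.0, 3.0, 4.0, 100.0]]))
        assert s.median == 3.0
        assert (s.q1, s.q3) == (2.0, 4.0)
        assert (s.whisker_low, s.whisker_high) == (1.0, 4.0)
        assert s.n_outliers == 1

    def test_quartiles_bracket_median_and_whiskers_bracket_quartiles(self, rng):
        s = boxwhisker_summary(rng.normal(size=(40, 40)))
        assert s.whisker_low <= s.q1 <= s.median <= s.q3 <= s.whisker_high

    def test_empty_mask_gives_flagged_empty_summary(self):
        s = boxwhisker_summary(np.ones((3, 3)), PixelMask(np.zeros((3, 3), bool)))
        assert s.empty and s.n_valid == 0

    def test_permutation_invariance_of_valid_set(self, rng):
        values = rng.normal(size=(20, 20))
        s1 = boxwhisker_summary(values)
        s2 = boxwhisker_summary(rng.permutation(values.ravel()).reshape(20, 20))
        assert (s1.median, s1.q1, s1.q3, s1.n_outliers) == (s2.median, s2.q1, s2.q3, s2.n_outliers)

    def test_single_layer_median_recovers_generator(self):
        stack, noise = scenario_presets("single")
        img, _ = generate_image(stack, NoiseSpec(noise.element_sigma, seed=7), (64, 64))
        dec = decompose_image(img, method="differential")
        s = boxwhisker_summary(dec.differential["Rt_deg"], dec.mask)
        assert s.median == pytest.approx(18.0, abs=1.0)


class TestAzimuthSummary:
    def test_uniform_scene_median(self):
        theta = np.full((10, 10), 90.0)
        rt = np.full((10, 10), 18.0)
        assert azimuth_summary(theta, rt).median == 90.0

    def test_crossed_equal_scene_is_nearly_empty(self):
        layer = LayerSpec(10.0, 1.8, 110.0, azimuth_jitter_deg=1.5, retardance_cv=0.05)
        stack = StackSpec([layer, layer], 90.0)
        img, _ = generate_image(stack, NoiseSpec(seed=5), (32, 32), share_fields=True)
        dec = decompose_image(img, method="differential")
        s = azimuth_summary(dec.differential["theta_deg"], dec.differential["Rt_deg"],
                            dec.mask, floor_deg=3.0)
        assert s.n_valid < 0.1 * dec.mask.n_valid()

    def test_floor_shrinks_spread_on_noisy_hole_rich_scene(self):
        layer = LayerSpec(10.0, 1.8, 90.0, azimuth_jitter_deg=1.5, retardance_cv=0.05,
                          hole_fraction=0.25, hole_radius_px=3)
        img, _ = generate_image(StackSpec([layer]), NoiseSpec(seed=6), (48, 48))
        dec = decompose_image(img, method="differential")
        s0 = azimuth_summary(dec.differential["theta_deg"], dec.differential["Rt_deg"],
                             dec.mask, floor_deg=0.0)
        s3 = azimuth_summary(dec.differential["theta_deg"], dec.differential["Rt_deg"],
                             dec.mask, floor_deg=3.0)
        assert (s3.q3 - s3.q1) < (s0.q3 - s0.q1)
        assert s3.n_valid < s0.n_valid

    def test_all_excluded_gives_empty_summary(self):
        theta = np.full((5, 5), 90.0)
        rt = np.full((5, 5), 1.0)
        assert azimuth_summary(theta, rt, floor_deg=3.0).empty

    def test_circular_median_handles_wraparound(self):
        angles = np.array([2.0, 4.0, 176.0, 178.0, 0.5])
        med = circular_median_deg(angles)
        assert fold_angle_difference_deg(med, 0.0) == pytest.approx(0.5, abs=2.0)


class TestQuiverExport:
    def test_constant_scene_counts_and_lengths(self):
        theta = np.full((100, 100), 45.0)
        rt = np.full((100, 100), 20.0)
        q = quiver_export(theta, rt, grid_step_px=20)
        assert len(q.sticks) == 25
        assert all(s[3] == 1.0 for s in q.sticks)
        assert all(s[2] == 45.0 for s in q.sticks)

    def test_stick_omitted_at_masked_grid_node(self):
        theta = np.full((40, 40), 45.0)
        rt = np.full((40, 40), 20.0)
        valid = np.ones((40, 40), bool)
        valid[20, 20] = False
        q = quiver_export(theta, rt, PixelMask(valid), grid_step_px=20)
        assert len(q.sticks) == 3
        assert (20, 20) not in {(s[0], s[1]) for s in q.sticks}

    def test_zero_retardance_gives_zero_lengths(self):
        q = quiver_export(np.full((20, 20), 10.0), np.zeros((20, 20)), grid_step_px=10)
        assert all(s[3] == 0.0 for s in q.sticks)

    def test_parallel_stack_sticks_cluster_near_generator_azimuth(self):
        stack, _ = scenario_presets("parallel")
        img, _ = generate_image(stack, NoiseSpec(seed=4), (64, 64))
        dec = decompose_image(img, method="lu_chipman")
        q = quiver_export(dec.lu_chipman["theta_deg"], dec.lu_chipman["Rt_deg"],
                          dec.mask, grid_step_px=20)
        angles = np.array([s[2] for s in q.sticks])
        spread = np.abs(fold_angle_difference_deg(angles, 110.0))
        assert np.median(spread) < 10.0


class TestCompareMethods:
    def test_identical_inputs_give_zero_difference(self):
        dec = decompose_image(_constant_scene(), method="both")
        maps, summary = compare_methods(dec.differential, dec.differential, dec.mask)
        assert summary.loc[0, "max_abs_dRt_deg"] == 0.0

    def test_noiseless_scene_methods_agree(self, noiseless_preset_decompositions):
        _, _, dec = noiseless_preset_decompositions["crossed45"]
        _, summary = compare_methods(dec.differential, dec.lu_chipman, dec.mask)
        assert summary.loc[0, "max_abs_dRt_deg"] < 0.1
        assert summary.loc[0, "max_abs_dtheta_deg"] < 0.1

    def test_isotropic_depolarizer_closed_form_mapping(self):
        a = 0.8
        pixels = np.broadcast_to(
            np.diag([1.0, a, a, a]) @ retarder_mueller(25.0, 60.0), (8, 8, 4, 4)
        ).copy()
        dec = decompose_image(MuellerImage(pixels), method="both")
        alpha_lc = dec.lu_chipman["alpha_t"]
        alpha_diff = dec.differential["alpha_t"]
        np.testing.assert_allclose(alpha_diff, -np.log(1 - alpha_lc), atol=1e-9)
        # Lu-Chipman values sit below the differential ones for a < 1
        assert np.all(alpha_lc < alpha_diff)

    def test_depolarization_rank_correlation_is_one_noiseless(
        self, noiseless_preset_decompositions
    ):
        _, _, dec = noiseless_preset_decompositions["single"]
        _, summary = compare_methods(dec.differential, dec.lu_chipman, dec.mask)
        assert summary.loc[0, "depol_spearman"] == pytest.approx(1.0, abs=1e-12)


def test_median_retardance_ordering_of_the_four_scenes(noiseless_preset_decompositions):
    """With layer-2 retardance half of layer-1 the medians order as
    parallel (27) > crossed45 (~20) > single (18) > crossed90 (9): composing
    18 and 9 deg retarders at 45 deg crossing exceeds the single layer."""
    med = {
        name: boxwhisker_summary(dec.differential["Rt_deg"], dec.mask).median
        for name, (_, _, dec) in noiseless_preset_decompositions.items()
    }
    assert med["parallel"] > med["crossed45"] > med["single"] > med["crossed90"]
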