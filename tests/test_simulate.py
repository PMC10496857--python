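"""Forward simulator: elementary matrices, stacks, scenes and presets."""
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from muellerpol import (
    depolarizer_mueller,
    differential_decompose,
    generate_image,
    is_physical,
    layer_mueller,
    lu_chipman_decompose,
    retarder_mueller,
    scenario_presets,
    stack_mueller,
)
from muellerpol.core import ContractError
from muellerpol.simulate import LayerSpec, NoiseSpec, StackSpec


class TestElementaryMatrices:
    def test_zero_retardance_is_identity(self):
        np.testing.assert_allclose(retarder_mueller(0.0, 37.0), np.eye(4), atol=1e-15)

    def test_half_wave_plate(self):
        np.testing.assert_allclose(
            retarder_mueller(180.0, 0.0), np.diag([1.0, 1.0, -1.0, -1.0]), atol=1e-15
        )

    @given(st.floats(1.0, 170.0), st.floats(0.0, 179.99))
    def test_retarder_round_trip_through_lu_chipman(self, delta, theta):
        p = lu_chipman_decompose(retarder_mueller(delta, theta))
        assert p.Rt == pytest.approx(delta, abs=1e-7)
        dtheta = (p.theta - theta + 90.0) % 180.0 - 90.0
        assert abs(dtheta) < 1e-7

    def test_depolarizer_identity_and_ideal(self):
        np.testing.assert_array_equal(depolarizer_mueller(1, 1, 1), np.eye(4))
        np.testing.assert_array_equal(
            depolarizer_mueller(0, 0, 0), np.diag([1.0, 0.0, 0.0, 0.0])
        )

    def test_isotropic_depolarizer_lu_chipman_alpha(self):
        p = lu_chipman_decompose(depolarizer_mueller(0.6, 0.6, 0.6))
        assert p.alpha_t == pytest.approx(0.4, abs=1e-12)

    @pytest.mark.parametrize("bad", [-0.1, 1.1])
    def test_depolarizer_contract(self, bad):
        with pytest.raises(ContractError):
            depolarizer_mueller(bad, 0.5, 0.5)


class TestLayerAndStack:
    def test_pure_retarder_layer(self):
        spec = LayerSpec(10.0, 1.8, 90.0)
        np.testing.assert_allclose(layer_mueller(spec), retarder_mueller(18.0, 90.0), atol=1e-12)

    def test_pure_depolarizer_layer(self):
        spec = LayerSpec(10.0, 0.0, 0.0, depol_per_um=0.02)
        a = np.exp(-0.2)
        np.testing.assert_allclose(layer_mueller(spec), depolarizer_mueller(a, a, a), atol=1e-12)

    def test_layer_factors_commute(self):
        spec = LayerSpec(10.0, 1.8, 40.0, depol_per_um=0.01)
        a = np.exp(-spec.depol_total)
        ret = retarder_mueller(18.0, 40.0)
        dep = depolarizer_mueller(a, a, a)
        np.testing.assert_allclose(dep @ ret, ret @ dep, atol=1e-14)
        np.testing.assert_allclose(layer_mueller(spec), dep @ ret, atol=1e-14)

    def test_ten_um_at_nominal_rate_gives_18_degrees(self):
        assert LayerSpec(10.0, 1.8, 90.0).delta_deg == pytest.approx(18.0)

    def test_retardance_leaving_principal_branch_rejected(self):
        with pytest.raises(ContractError, match="principal branch"):
            LayerSpec(101.0, 1.8, 0.0)

    def test_parallel_layers_add(self):
        st_ = StackSpec([LayerSpec(10.0, 1.8, 30.0), LayerSpec(5.0, 1.8, 30.0)], 0.0)
        assert differential_decompose(stack_mueller(st_)).Rt == pytest.approx(27.0, abs=1e-9)

    def test_crossed_equal_layers_compensate(self):
        st_ = StackSpec([LayerSpec(10.0, 1.8, 0.0), LayerSpec(10.0, 1.8, 0.0)], 90.0)
        assert differential_decompose(stack_mueller(st_)).Rt == pytest.approx(0.0, abs=1e-8)

    def test_crossed_unequal_layers_subtract(self):
        st_ = StackSpec([LayerSpec(10.0, 1.8, 0.0), LayerSpec(5.0, 1.8, 0.0)], 90.0)
        assert differential_decompose(stack_mueller(st_)).Rt == pytest.approx(9.0, abs=1e-9)


class TestGenerateImage:
    def test_noiseless_homogeneous_scene_recovers_ground_truth(self):
        layer = LayerSpec(10.0, 1.8, 90.0)
        img, truth = generate_image(StackSpec([layer]), NoiseSpec(0.0, seed=1), (8, 8))
        for M, rt, th in zip(
            img.pixels.reshape(-1, 4, 4),
            truth["Rt_deg"].ravel(),
            truth["theta_deg"].ravel(),
        ):
            p = differential_decompose(M)
            assert p.Rt == pytest.approx(rt, abs=1e-6)
            assert p.theta == pytest.approx(th, abs=1e-6)

    def test_noiseless_outputs_are_physical_and_passive(self):
        stack, _ = scenario_presets("crossed45")
        img, _ = generate_image(stack, NoiseSpec(0.0, seed=3), (16, 16))
        assert bool(np.all(is_physical(img.pixels)))
        m11 = img.pixels[..., 0, 0][..., None, None]
        assert np.all(np.abs(img.pixels) <= m11 + 1e-12)

    def test_seed_determinism(self):
        stack, noise = scenario_presets("single")
        img1, t1 = generate_image(stack, noise, (16, 16))
        img2, t2 = generate_image(stack, noise, (16, 16))
        np.testing.assert_array_equal(img1.pixels, img2.pixels)
        np.testing.assert_array_equal(t1["Rt_deg"], t2["Rt_deg"])

    def test_two_seeds_differ_pixelwise_but_agree_statistically(self):
        stack, _ = scenario_presets("single")
        img1, _ = generate_image(stack, NoiseSpec(seed=5), (48, 48))
        img2, _ = generate_image(stack, NoiseSpec(seed=6), (48, 48))
        assert np.abs(img1.pixels - img2.pixels).max() > 0
        from muellerpol import decompose_image

        m1 = np.nanmedian(decompose_image(img1, "differential").differential["Rt_deg"])
        m2 = np.nanmedian(decompose_image(img2, "differential").differential["Rt_deg"])
        assert abs(m1 - m2) < 2.5  # below the noise floor

    def test_holes_carry_no_retardance_in_truth(self):
        layer = LayerSpec(10.0, 1.8, 90.0, hole_fraction=0.2, hole_radius_px=2)
        _, truth = generate_image(StackSpec([layer]), NoiseSpec(0.0, seed=2), (32, 32))
        assert truth["holes"].any()
        assert np.all(truth["Rt_deg"][truth["holes"]] < 1e-9)

    def test_shared_fields_make_crossed_equal_layers_cancel(self):
        layer = LayerSpec(10.0, 1.8, 110.0, azimuth_jitter_deg=5.0, retardance_cv=0.1)
        stack = StackSpec([layer, layer], 90.0)
        _, truth = generate_image(stack, NoiseSpec(0.0, seed=4), (16, 16), share_fields=True)
        assert np.nanmax(truth["Rt_deg"]) < 1e-8

    def test_tiny_scene_rejected(self):
        with pytest.raises(ContractError):
            generate_image(StackSpec([LayerSpec(10.0, 1.8, 0.0)]), NoiseSpec(0.0, 0), (4, 4))


class TestPresets:
    def test_single_preset_geometry(self):
        stack, noise = scenario_presets("single")
        assert len(stack.layers) == 1
        assert stack.layers[0].thickness_um == 10.0
        assert stack.layers[0].delta_deg == pytest.approx(18.0)
        assert stack.layers[0].azimuth_deg == 90.0
        assert noise.element_sigma > 0

    def test_crossed90_preset_crossing_angle(self):
        stack, _ = scenario_presets("crossed90")
        assert stack.crossing_angle_deg == 90.0
        assert [l.thickness_um for l in stack.layers] == [10.0, 5.0]

    def test_unknown_preset_rejected(self):
        with pytest.raises(ContractError):
            scenario_presets("sideways")

    def test_stack_depolarization_exceeds_single_by_2p5_to_3x(self):
        single, _ = scenario_presets("single")
        stack, _ = scenario_presets("parallel")
        a_single = sum(l.depol_total for l in single.layers)
        a_stack = sum(l.depol_total for l in stack.layers)
        assert 2.5 <= a_stack / a_single <= 3.0
        # and in the Lu-Chipman convention as well
        lc_ratio = (1 - np.exp(-a_stack)) / (1 - np.exp(-a_single))
        assert 2.5 <= lc_ratio <= 3.0

    def test_parallel_median_exceeds_single(self):
        from muellerpol import decompose_image

        med = {}
        for name in ("single", "parallel"):
            stack, _ = scenario_presets(name)
            img, _ = generate_image(stack, NoiseSpec(0.0, seed=8), (32, 32))
            med[name] = np.nanmedian(decompose_image(img, "differential").differential["Rt_deg"])
        assert med["parallel"] > med["single"]


def test_depolarization_invariant_under_crossing_angle():
    """Stack depolarization tracks thickness, not fiber crossing: noiseless
    relative spread across crossing angles is ~0, and stays below 15% with
    the default measurement noise."""
    from muellerpol import decompose_image

    for sigma, limit in ((0.0, 1e-9), (None, 0.15)):
        medians = []
        for name in ("parallel", "crossed45", "crossed90"):
            stack, noise = scenario_presets(name)
            ns = NoiseSpec(0.0 if sigma == 0.0 else noise.element_sigma, seed=9)
            img, _ = generate_image(stack, ns, (32, 32))
            dec = decompose_image(img, "differential")
            medians.append(np.nanmedian(dec.differential["alpha_t"]))
        spread = (max(medians) - min(medians)) / min(medians)
        assert spread < limit
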