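"""Network architecture: modulation, pooling, fusion, forward pass."""

import numpy as np
import pytest

from conftest import numeric_gradient
from lcmqsm import autodiff as ad
from lcmqsm.autodiff import Tensor
from lcmqsm.geometry import ValidationError
from lcmqsm.model import (
    LCMnet,
    LCMnetConfig,
    LatentCode,
    demodulate_weights,
    downsample_mask,
    lcmnet_forward,
    modulate_weights,
)
from lcmqsm.training import LossConfig, training_loss


def tiny_config(**flags):
    return LCMnetConfig(n_encoder_levels=2, base_channels=4, **flags)


def tiny_inputs(shape=(8, 8, 8), seed=0):
    rng = np.random.default_rng(seed)
    field = 0.01 * rng.standard_normal(shape)
    mag = rng.uniform(0, 1, shape)
    chi_init = 0.1 * rng.standard_normal(shape)
    mask = np.zeros(shape, bool)
    mask[shape[0] // 4 :, :, :] = True  # survives the 4x pooled 0.5 threshold
    return field * mask, mag * mask, chi_init * mask, mask


class TestModulation:
    def test_identity_latent_leaves_weights_unchanged(self, rng):
        w = rng.standard_normal((3, 4, 3, 3, 3))
        assert np.array_equal(modulate_weights(w, np.ones(4)), w)

    def test_single_channel_scaling(self, rng):
        w = rng.standard_normal((3, 4, 3, 3, 3))
        latent = np.ones(4)
        latent[2] = 2.0
        w2 = modulate_weights(w, LatentCode(latent, block_index=0))
        assert np.array_equal(w2[:, 2], 2.0 * w[:, 2])
        other = [0, 1, 3]
        assert np.array_equal(w2[:, other], w[:, other])

    def test_matches_five_nested_loop_oracle(self, rng):
        w = rng.standard_normal((4, 4, 3, 3, 3))
        latent = rng.standard_normal(4)
        got = modulate_weights(w, latent)
        expected = np.empty_like(w)
        for o in range(4):
            for c in range(4):
                for p in range(3):
                    for q in range(3):
                        for r in range(3):
                            expected[o, c, p, q, r] = latent[c] * w[o, c, p, q, r]
        assert np.max(np.abs(got - expected)) < 1e-15

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(ValidationError):
            modulate_weights(rng.standard_normal((3, 4, 3, 3, 3)), np.ones(5))


class TestDemodulation:
    def test_zero_weights_stay_zero_and_finite(self):
        w = np.zeros((2, 3, 3, 3, 3))
        out = demodulate_weights(w, 1e-8)
        assert np.all(np.isfinite(out)) and np.all(out == 0)

    def test_per_output_channel_norm_identity(self, rng):
        """After demodulation, sum w''^2 = s/(s+eps) per output channel."""
        eps = 1e-8
        w = rng.standard_normal((5, 3, 3, 3, 3))
        out = demodulate_weights(w, eps)
        s = (w**2).sum(axis=(1, 2, 3, 4))
        norms = (out**2).sum(axis=(1, 2, 3, 4))
        assert np.max(np.abs(norms - s / (s + eps))) < 1e-10
        assert np.all(norms < 1.0)
        assert np.all(norms >= 1 - eps / (s + eps) - 1e-12)

    def test_matches_scalar_loop_oracle(self, rng):
        eps = 1e-8
        w = rng.standard_normal((2, 2, 3, 3, 3))
        got = demodulate_weights(w, eps)
        expected = np.empty_like(w)
        for o in range(2):
            s = 0.0
            for c in range(2):
                for p in range(3):
                    for q in range(3):
                        for r in range(3):
                            s += w[o, c, p, q, r] ** 2
            expected[o] = w[o] / np.sqrt(s + eps)
        assert np.max(np.abs(got - expected)) < 1e-12

    def test_invalid_epsilon_rejected(self, rng):
        with pytest.raises(ValidationError):
            demodulate_weights(rng.standard_normal((2, 2, 3, 3, 3)), 0.0)


def test_modulated_conv_micro_instance_hand_computed(rng):
    """1-voxel patch, 1x1x1 kernel: modulated conv is a 2x2 matrix product."""
    eps = 1e-8
    w = rng.standard_normal((2, 2, 1, 1, 1))
    latent = np.array([1.5, 0.5])
    x = rng.standard_normal((2, 1, 1, 1))
    w2 = demodulate_weights(modulate_weights(w, latent), eps)
    y = ad.conv3d(Tensor(x), Tensor(w2)).data
    W = w[:, :, 0, 0, 0] * latent[None, :]
    W = W / np.sqrt((W**2).sum(axis=1, keepdims=True) + eps)
    expected = W @ x[:, 0, 0, 0]
    assert np.allclose(y[:, 0, 0, 0], expected, atol=1e-12)


class TestEncoderDecoder:
    def test_structure_and_bottleneck_shape(self):
        model = LCMnet(tiny_config(), seed=0)
        feats = model.encode_field(np.zeros((16, 16, 16)))
        assert len(feats["levels"]) == 2
        assert all(f.data.shape == (4, 16, 16, 16) for f in feats["levels"])
        assert feats["bottleneck"].data.shape == (8, 4, 4, 4)

    def test_zero_input_zero_biases_gives_zero_features(self):
        model = LCMnet(tiny_config(), seed=0)  # biases init to zero
        feats = model.encode_field(np.zeros((8, 8, 8)))
        assert np.all(feats["bottleneck"].data == 0)
        assert all(np.all(f.data == 0) for f in feats["levels"])

    def test_indivisible_patch_rejected_with_multiple_named(self):
        model = LCMnet(tiny_config(), seed=0)
        with pytest.raises(ValidationError, match="multiples of 4"):
            model.encode_field(np.zeros((10, 8, 8)))

    def test_latent_code_lengths_match_block_channels(self):
        cfg = tiny_config()
        model = LCMnet(cfg, seed=0)
        feats = model.encode_field(np.zeros((8, 8, 8)))
        mask = np.ones((8, 8, 8), bool)
        codes = model.decode_latent(feats["bottleneck"], mask)
        assert len(codes) == cfg.n_modulated_blocks
        assert all(c.data.shape == (cfg.base_channels,) for c in codes)

    def test_empty_downsampled_mask_rejected(self):
        model = LCMnet(tiny_config(), seed=0)
        feats = model.encode_field(np.zeros((8, 8, 8)))
        mask = np.zeros((8, 8, 8), bool)
        mask[0, 0, 0] = True  # vanishes after 4x mean-pool threshold
        with pytest.raises(ValidationError):
            model.decode_latent(feats["bottleneck"], mask)


class TestMaskedPooling:
    def test_downsample_mask_majority_threshold(self):
        m = np.zeros((4, 4, 4), bool)
        m[:2, :2, :2] = True  # one fully-true 2x2x2 block
        out = downsample_mask(m, 2)
        assert out[0, 0, 0] and out.sum() == 1

    def test_pooled_value_ignores_background(self, rng):
        """Constant c inside VOI, garbage outside -> pooled mean is c."""
        mask = np.zeros((8, 8, 8), bool)
        mask[0:4, 0:4, 0:4] = True
        pooled_mask = downsample_mask(mask, 4)
        feat = np.where(pooled_mask, 3.25, rng.standard_normal((2, 2, 2)) * 100)
        count = pooled_mask.sum()
        pooled = (feat * pooled_mask).sum() / count
        assert pooled == 3.25

    def test_masked_mean_matches_sum_over_true_voxels(self, rng):
        feat = rng.standard_normal((3, 2, 2, 2))
        pooled_mask = np.zeros((2, 2, 2), bool)
        pooled_mask[0, 1, 0] = pooled_mask[1, 0, 1] = True
        m = pooled_mask[None].astype(float)
        got = (Tensor(feat) * m).sum(axis=(1, 2, 3)) * (1.0 / pooled_mask.sum())
        expected = np.array([
            sum(feat[c][idx] for idx in zip(*np.where(pooled_mask))) / 2
            for c in range(3)
        ])
        assert np.allclose(got.data, expected, atol=1e-14)

    def test_latent_codes_invariant_to_background_perturbation(self, rng):
        model = LCMnet(tiny_config(), seed=1)
        field, mag, chi_init, mask = tiny_inputs()
        feats = model.encode_field(field)
        codes_a = model.decode_latent(feats["bottleneck"], mask)
        perturbed = feats["bottleneck"].data.copy()
        pooled_mask = downsample_mask(mask, 4)
        perturbed[:, ~pooled_mask] += 1e6 * rng.standard_normal(
            perturbed[:, ~pooled_mask].shape
        )
        codes_b = model.decode_latent(Tensor(perturbed), mask)
        for a, b in zip(codes_a, codes_b):
            assert np.array_equal(a.data, b.data)


class TestCrossFusion:
    def test_outputs_match_levels_and_shapes(self):
        model = LCMnet(tiny_config(), seed=0)
        field, mag, _, mask = tiny_inputs()
        feats = model.encode_field(field)
        fused = model.cross_fusion(feats, mag, mask)
        assert len(fused) == 2
        assert all(f.data.shape == (4, 8, 8, 8) for f in fused)

    def test_background_magnitude_never_influences_output(self, rng):
        model = LCMnet(tiny_config(), seed=0)
        field, mag, _, mask = tiny_inputs()
        feats = model.encode_field(field)
        a = model.cross_fusion(feats, mag, mask)
        mag_b = mag.copy()
        mag_b[~mask] += rng.standard_normal((~mask).sum()) * 50
        b = model.cross_fusion(feats, mag_b, mask)
        for fa, fb in zip(a, b):
            assert np.array_equal(fa.data, fb.data)

    def test_no_fusion_variant_independent_of_magnitude(self, rng):
        model = LCMnet(tiny_config(no_fusion=True), seed=0)
        field, mag, _, mask = tiny_inputs()
        feats = model.encode_field(field)
        a = model.cross_fusion(feats, mag, mask)
        b = model.cross_fusion(feats, rng.uniform(0, 1, mag.shape), mask)
        for fa, fb in zip(a, b):
            assert np.array_equal(fa.data, fb.data)


class TestForward:
    @pytest.mark.parametrize("shape", [(8, 8, 8), (16, 16, 16), (8, 16, 12)])
    def test_output_shape_matches_input(self, shape):
        model = LCMnet(tiny_config(), seed=0)
        out = lcmnet_forward(model, *tiny_inputs(shape))
        assert out.shape == shape

    def test_inference_is_deterministic(self):
        model = LCMnet(tiny_config(), seed=0)
        inputs = tiny_inputs()
        a = lcmnet_forward(model, *inputs)
        b = lcmnet_forward(model, *inputs)
        assert np.array_equal(a, b)

    def test_shape_mismatch_rejected(self):
        model = LCMnet(tiny_config(), seed=0)
        field, mag, chi_init, mask = tiny_inputs()
        with pytest.raises(ValidationError):
            model.forward(field, mag[:4], chi_init, mask)

    def test_output_inside_voi_invariant_to_outside_perturbation(self, rng):
        """Pre-masked inputs: garbage outside the VOI cannot leak inside."""
        model = LCMnet(tiny_config(), seed=2)
        field, mag, chi_init, mask = tiny_inputs()
        base = lcmnet_forward(model, field, mag, chi_init, mask)
        noise = lambda: rng.standard_normal(field.shape) * 10
        field_b = (field + noise() * ~mask) * mask
        mag_b = (mag + noise() * ~mask) * mask
        chi_b = (chi_init + noise() * ~mask) * mask
        out = lcmnet_forward(model, field_b, mag_b, chi_b, mask)
        assert np.array_equal(base, out)

    def test_plain_network_reduction_ignores_magnitude_and_chi_init(self, rng):
        """no_mod + no_fusion + field-as-input strips all extra pathways."""
        cfg = tiny_config(no_modulation=True, no_fusion=True,
                          field_as_initial_input=True)
        model = LCMnet(cfg, seed=0)
        field, mag, chi_init, mask = tiny_inputs()
        a = model.forward(field, mag, chi_init, mask).data
        b = model.forward(field, rng.uniform(0, 1, mag.shape) * mask,
                          rng.standard_normal(chi_init.shape) * mask, mask).data
        assert np.array_equal(a, b)

    def test_delta_b_variant_ignores_chi_init(self, rng):
        model = LCMnet(tiny_config(field_as_initial_input=True), seed=0)
        field, mag, chi_init, mask = tiny_inputs()
        a = model.forward(field, mag, chi_init, mask).data
        b = model.forward(field, mag, rng.standard_normal(chi_init.shape) * mask,
                          mask).data
        assert np.array_equal(a, b)

    def test_chi_init_residual_flag(self):
        field, mag, chi_init, mask = tiny_inputs()
        plain = LCMnet(tiny_config(), seed=0).forward(field, mag, chi_init, mask).data
        res = LCMnet(tiny_config(chi_init_residual=True), seed=0).forward(
            field, mag, chi_init, mask).data
        assert np.allclose(res, plain + chi_init, atol=1e-12)


def test_full_model_gradients_match_finite_differences():
    """Loss gradient wrt modulated-block and latent-head weights, 4^3 patch."""
    cfg = tiny_config()
    model = LCMnet(cfg, seed=3)
    rng = np.random.default_rng(5)
    shape = (4, 4, 4)
    field = 0.01 * rng.standard_normal(shape)
    mag = rng.uniform(0, 1, shape)
    chi_init = 0.1 * rng.standard_normal(shape)
    chi_ref = 0.1 * rng.standard_normal(shape)
    mask = np.ones(shape, bool)
    loss_cfg = LossConfig(alpha=1.0, log_sigma=1.0, log_kernel_size=3)

    def loss_value():
        pred = model.forward(field, mag, chi_init, mask)
        return training_loss(pred, chi_ref, mask, loss_cfg)

    loss = loss_value()
    loss.backward()
    rng_idx = np.random.default_rng(0)
    for name in ("mod0_w", "mod1_w", "lat0_w", "enc0_w", "comb0_w", "head_w"):
        p = model.params[name]
        analytic = p.grad
        assert analytic is not None
        flat = np.argsort(np.abs(analytic).ravel())[-3:]  # strongest entries
        for k in flat:
            idx = np.unravel_index(k, p.data.shape)
            orig = p.data[idx]
            eps = 1e-5 * max(1.0, abs(orig))
            p.data[idx] = orig + eps
            up = float(loss_value().data)
            p.data[idx] = orig - eps
            down = float(loss_value().data)
            p.data[idx] = orig
            numeric = (up - down) / (2 * eps)
            assert numeric == pytest.approx(analytic[idx], rel=1e-4, abs=1e-10)


def test_checkpoint_round_trip(tmp_path):
    model = LCMnet(tiny_config(no_fusion=True), seed=0)
    inputs = tiny_inputs()
    before = lcmnet_forward(model, *inputs)
    path = tmp_path / "model.npz"
    model.save(path)
    loaded = LCMnet.load(path)
    assert loaded.config == model.config
    assert np.array_equal(lcmnet_forward(loaded, *inputs), before)


def test_config_validation():
    with pytest.raises(ValidationError):
        LCMnetConfig(n_modulated_blocks=6)
    with pytest.raises(ValidationError):
        LCMnetConfig(epsilon=0.0)
    with pytest.raises(ValidationError):
        LCMnetConfig(kernel_size=4)
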