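"""Tests for the gated-fusion transformer: blocks, loss, training loop."""

import numpy as np
import pytest

from spadkit.nn import (
    DCSTB, GatedFusion, LossConfig, NetworkConfig, OptimizerConfig,
    RandomConvFeatures, ShallowExtractor, Tensor, build_model, enhance,
    hybrid_loss, l1_loss, learning_rate_at_epoch, load_checkpoint,
    perceptual_loss, save_checkpoint, ssim, ssim_loss, train,
)
from spadkit.nn.layers import WindowAttention, _window_partition


def _rng_tensor(shape, seed=0, requires_grad=False):
    return Tensor(np.random.default_rng(seed).random(shape),
                  requires_grad=requires_grad)


SMALL = NetworkConfig(embed_dim=8, n_blocks=2, layers_per_block=2,
                      window_size=4, n_heads=2, sr_scale=2)


class TestBlocks:
    def test_shallow_extractor_output_shape(self):
        mod = ShallowExtractor(SMALL, np.random.default_rng(0))
        out = mod(_rng_tensor((3, 1, 8, 12)))
        assert out.shape == (3, 8, 8, 12)

    def test_zero_input_zero_bias_gives_spatially_constant_features(self):
        mod = ShallowExtractor(SMALL, np.random.default_rng(0)).eval()
        out = mod(Tensor(np.zeros((1, 1, 8, 8)))).data
        assert np.allclose(out, out[..., :1, :1])

    def test_dcstb_preserves_shape_and_is_batch_equivariant(self):
        block = DCSTB(2, SMALL, np.random.default_rng(1)).eval()
        f0 = _rng_tensor((2, 8, 8, 8), seed=2)
        f1 = _rng_tensor((2, 8, 8, 8), seed=3)
        out = block([f0, f1]).data
        assert out.shape == (2, 8, 8, 8)
        swapped = block([Tensor(f0.data[::-1].copy()),
                         Tensor(f1.data[::-1].copy())]).data
        assert np.allclose(out, swapped[::-1], atol=1e-10)

    def test_attention_rows_are_normalized(self):
        attn_mod = WindowAttention(8, 2, np.random.default_rng(4))
        tokens = _rng_tensor((6, 16, 8), seed=5)
        _, attn = attn_mod(tokens, return_attn=True)
        assert np.allclose(attn.data.sum(axis=-1), 1.0)

    def test_window_partition_requires_divisible_sides(self):
        with pytest.raises(ValueError, match="divisible"):
            _window_partition(_rng_tensor((1, 8, 6, 6)), 4)


class TestGatedFusion:
    def test_zero_gates_give_zero(self):
        gf = GatedFusion(3)
        gf.set_gates([0.0, 0.0, 0.0])
        feats = [_rng_tensor((1, 4, 8, 8), seed=i) for i in range(3)]
        assert np.all(gf(feats).data == 0.0)

    def test_one_hot_gate_selects_exactly_one_feature(self):
        gf = GatedFusion(3)
        gf.set_gates([0.0, 1.0, 0.0])
        feats = [_rng_tensor((1, 4, 8, 8), seed=i) for i in range(3)]
        assert np.array_equal(gf(feats).data, feats[1].data)

    def test_linearity_in_features(self):
        gf = GatedFusion(2)
        gf.set_gates([0.3, -0.7])
        feats = [_rng_tensor((1, 2, 4, 4), seed=i) for i in range(2)]
        doubled = [Tensor(2 * f.data) for f in feats]
        assert np.allclose(gf(doubled).data, 2 * gf(feats).data)

    def test_count_mismatch_rejected(self):
        with pytest.raises(ValueError, match="feature maps"):
            GatedFusion(2)([_rng_tensor((1, 2, 4, 4))])

    def test_gates_receive_gradients(self):
        model = build_model(SMALL, seed=0)
        x = _rng_tensor((2, 1, 8, 8), seed=6)
        y = _rng_tensor((2, 1, 16, 16), seed=7)
        loss = hybrid_loss(model(x), y,
                           LossConfig(alpha=1.0, beta=0.0, gamma=0.0))
        loss.backward()
        for g in model.fusion.gates:
            assert g.grad is not None and g.grad != 0.0


class TestReconstruction:
    def test_scale_4_output_shape(self):
        cfg = NetworkConfig(embed_dim=8, n_blocks=1, layers_per_block=2,
                            window_size=4, n_heads=2, sr_scale=4)
        model = build_model(cfg, seed=1)
        out = model(_rng_tensor((1, 1, 32, 64), seed=8))
        assert out.shape == (1, 1, 128, 256)

    def test_scale_1_preserves_shape(self):
        cfg = NetworkConfig(embed_dim=8, n_blocks=1, layers_per_block=1,
                            window_size=4, n_heads=2, sr_scale=1)
        out = build_model(cfg, seed=1)(_rng_tensor((1, 1, 8, 8)))
        assert out.shape == (1, 1, 8, 8)
        assert np.all(np.isfinite(out.data))

    def test_invalid_scale_rejected(self):
        with pytest.raises(ValueError, match="sr_scale"):
            NetworkConfig(sr_scale=3)


class TestHybridLoss:
    def test_identical_images_give_zero_loss(self):
        img = _rng_tensor((1, 1, 16, 16), seed=9)
        cfg = LossConfig().with_default_extractor()
        assert hybrid_loss(img, Tensor(img.data.copy()), cfg).item() == \
            pytest.approx(0.0, abs=1e-12)

    def test_gamma_only_equals_ssim_loss(self):
        a = _rng_tensor((1, 1, 16, 16), seed=10)
        b = _rng_tensor((1, 1, 16, 16), seed=11)
        cfg = LossConfig(alpha=0.0, beta=0.0, gamma=1.0)
        assert hybrid_loss(a, b, cfg).item() == \
            pytest.approx(ssim_loss(a, b).item())

    def test_decomposes_into_weighted_terms(self):
        a = _rng_tensor((1, 1, 16, 16), seed=12)
        b = _rng_tensor((1, 1, 16, 16), seed=13)
        phi = RandomConvFeatures(seed=7)
        cfg = LossConfig(alpha=0.1, beta=10.0, gamma=100.0,
                         perceptual_extractor=phi)
        total = hybrid_loss(a, b, cfg).item()
        parts = (0.1 * l1_loss(a, b).item()
                 + 10.0 * perceptual_loss(a, b, phi).item()
                 + 100.0 * ssim_loss(a, b).item())
        assert total == pytest.approx(parts, rel=1e-12)

    def test_default_weights(self):
        cfg = LossConfig()
        assert (cfg.alpha, cfg.beta, cfg.gamma) == (0.1, 10.0, 100.0)

    def test_missing_extractor_with_beta_rejected(self):
        a = _rng_tensor((1, 1, 16, 16))
        with pytest.raises(ValueError, match="extractor"):
            hybrid_loss(a, a, LossConfig(beta=1.0))

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            LossConfig(alpha=0.0, beta=0.0, gamma=0.0)

    def test_ssim_window_larger_than_image_rejected(self):
        a = _rng_tensor((1, 1, 8, 8))
        with pytest.raises(ValueError, match="window"):
            ssim(a, a)


class TestTraining:
    def test_lr_schedule_decays_ten_percent_per_100_epochs(self):
        cfg = OptimizerConfig()
        assert learning_rate_at_epoch(cfg, 0) == pytest.approx(3e-4)
        assert learning_rate_at_epoch(cfg, 99) == pytest.approx(3e-4)
        assert learning_rate_at_epoch(cfg, 100) == pytest.approx(0.9 * 3e-4)
        assert learning_rate_at_epoch(cfg, 250) == pytest.approx(0.81 * 3e-4)

    def test_fixed_seed_gives_identical_first_step_gradients(self, toy_pairs):
        grads = []
        for _ in range(2):
            model = build_model(SMALL, seed=5)
            lq, hr = toy_pairs[0]
            loss = hybrid_loss(
                model(Tensor(lq[None, None])), Tensor(hr[None, None]),
                LossConfig().with_default_extractor())
            loss.backward()
            grads.append(np.concatenate([p.grad.ravel()
                                         for p in model.parameters()]))
        assert np.array_equal(grads[0], grads[1])

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            train([], SMALL, n_steps=1)

    def test_non_finite_loss_aborts_with_diagnostics(self):
        bad = [(np.full((8, 8), np.nan), np.zeros((16, 16)))]
        with pytest.raises(RuntimeError, match="non-finite"):
            train(bad, SMALL, n_steps=2, seed=0)

    def test_short_run_reduces_loss(self, toy_pairs):
        res = train(toy_pairs[:4], SMALL, seed=1, n_steps=25)
        assert res.final_loss < res.initial_loss

    def test_checkpoint_round_trip_is_bit_identical(self, tmp_path, toy_pairs):
        res = train(toy_pairs[:2], SMALL, seed=2, n_steps=5)
        lq = toy_pairs[0][0]
        before = enhance(lq, res.model)
        save_checkpoint(res.model, tmp_path / "ckpt")
        reloaded = load_checkpoint(tmp_path / "ckpt")
        assert np.array_equal(before, enhance(lq, reloaded))


class TestEnhance:
    def test_output_range_and_scale_contract(self, toy_training, toy_pairs):
        lq = toy_pairs[0][0]
        out = enhance(lq, toy_training.model)
        assert out.shape == (32, 32)
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_window_mismatch_rejected(self, toy_training):
        with pytest.raises(ValueError, match="window"):
            enhance(np.zeros((10, 10)), toy_training.model)
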