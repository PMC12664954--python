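"""Full-model contracts: shapes, parameter budgets, MAC profile, bridges,
gradient flow."""

import numpy as np
import pytest

from ultralight_vmunet import (ModelConfig, bce_dice_loss, build_model,
                               enumerate_params, flops_count)
from ultralight_vmunet.model import (ChannelAttentionBridge, ConvBlock,
                                     PVMStage, SpatialAttentionBridge)
from ultralight_vmunet.nn import Tensor
from ultralight_vmunet.nn import functional as Fn


class TestConvBlock:
    def test_shape_and_parameter_count(self, rng):
        block = ConvBlock(3, 8)
        x = rng.standard_normal((1, 3, 32, 32)).astype(np.float32)
        pooled = Fn.max_pool2x2(block(x))
        assert pooled.shape == (1, 8, 16, 16)
        assert enumerate_params(block).total == 3 * 8 * 9 + 8  # 224

    def test_zero_input_passes_bias_through(self):
        block = ConvBlock(3, 4)
        out = block(np.zeros((1, 3, 8, 8), dtype=np.float32)).data
        expected = np.broadcast_to(block.conv.bias.data[None, :, None, None],
                                   out.shape)
        np.testing.assert_allclose(out, expected, atol=1e-7)


class TestPVMStage:
    def test_token_roundtrip_is_identity(self, rng):
        from ultralight_vmunet.model import _to_map, _to_tokens
        x = Tensor(rng.standard_normal((2, 5, 4, 6)))
        tokens, hw = _to_tokens(x)
        np.testing.assert_array_equal(_to_map(tokens, hw).data, x.data)

    def test_encoder_stage4_shape(self, rng):
        stage = PVMStage(24, 32, k=4, conv_mode="depthwise")
        x = rng.standard_normal((1, 24, 32, 32)).astype(np.float32)
        out = Fn.max_pool2x2(stage(x))
        assert out.shape == (1, 32, 16, 16)

    def test_stage4_branch_width_resolves_unit_dt_rank(self):
        stage = PVMStage(24, 32, k=4, conv_mode="depthwise")
        cfg = stage.pvm.mamba.cfg
        assert cfg.d_model == 6
        assert cfg.dt_rank_resolved == 1


class TestBridges:
    def _features(self, rng, channels=(8, 16, 24), size=16):
        return [Tensor(rng.standard_normal((2, c, size // 2 ** i, size // 2 ** i))
                       .astype(np.float32))
                for i, c in enumerate(channels)]

    def test_sab_gate_in_unit_interval_and_shapes_kept(self, rng):
        sab = SpatialAttentionBridge()
        feats = self._features(rng)
        out = sab(feats)
        for before, after in zip(feats, out):
            assert after.shape == before.shape
            # gate*x + x stays within [x, 2x] envelope elementwise
            lo = np.minimum(before.data, 2 * before.data)
            hi = np.maximum(before.data, 2 * before.data)
            assert np.all(after.data >= lo - 1e-6)
            assert np.all(after.data <= hi + 1e-6)

    def test_sab_saturated_gate_doubles_input(self, rng):
        """Driving the shared conv output to a large constant makes the
        sigmoid gate ~1, so the bridge returns ~2x its input."""
        sab = SpatialAttentionBridge()
        sab.shared_conv.weight.data = np.zeros_like(sab.shared_conv.weight.data)
        sab.shared_conv.bias.data = np.full_like(sab.shared_conv.bias.data, 50.0)
        feats = self._features(rng)
        out = sab(feats)
        for before, after in zip(feats, out):
            np.testing.assert_allclose(after.data, 2 * before.data, rtol=1e-6)

    def test_cab_shapes_and_zero_input(self, rng):
        cab = ChannelAttentionBridge([8, 16, 24])
        feats = self._features(rng)
        out = cab(feats)
        for before, after in zip(feats, out):
            assert after.shape == before.shape
        zero = [Tensor(np.zeros_like(f.data)) for f in feats]
        for after in cab(zero):
            assert np.all(after.data == 0)  # gates scale zeros, residual zero

    def test_cab_gate_locality(self, rng):
        """Scaling stage 2's gate affects only stage 2's output."""
        cab = ChannelAttentionBridge([8, 16, 24])
        feats = self._features(rng)
        base = [o.data.copy() for o in cab(feats)]
        cab.atts[1].bias.data = cab.atts[1].bias.data + 5.0
        after = [o.data for o in cab(feats)]
        np.testing.assert_array_equal(base[0], after[0])
        np.testing.assert_array_equal(base[2], after[2])
        assert not np.allclose(base[1], after[1])


class TestModel:
    @pytest.mark.parametrize("cfg,expected_millions", [
        (ModelConfig(), 0.049),
        (ModelConfig(k=2), 0.070),
        (ModelConfig(k=1), 0.136),
        (ModelConfig(bridges=False), 0.033),
    ])
    def test_parameter_budgets_match_published_totals(self, cfg, expected_millions):
        model = build_model(cfg, seed=0)
        assert round(model.num_parameters() / 1e6, 3) == expected_millions

    def test_default_budget_exact_count(self):
        assert build_model(ModelConfig(), seed=0).num_parameters() == 49_454

    @pytest.mark.parametrize("bridges,expected", [(True, 0.060), (False, 0.058)])
    def test_gflops_at_256(self, bridges, expected):
        model = build_model(ModelConfig(bridges=bridges), seed=0)
        assert round(flops_count(model, (3, 256, 256)), 3) == expected

    def test_forward_shape_and_range(self, rng):
        model = build_model(ModelConfig(input_size=64), seed=0)
        x = rng.random((2, 3, 64, 64)).astype(np.float32)
        out = model(x)
        assert out.shape == (2, 1, 64, 64)
        assert np.all(out.data >= 0) and np.all(out.data <= 1)

    def test_forward_deterministic(self, rng):
        model = build_model(ModelConfig(input_size=64), seed=0)
        x = rng.random((1, 3, 64, 64)).astype(np.float32)
        np.testing.assert_array_equal(model(x).data, model(x).data)

    def test_invalid_input_side_raises(self, rng):
        model = build_model(ModelConfig(), seed=0)
        with pytest.raises(ValueError):
            model(rng.random((1, 3, 48, 48)).astype(np.float32))
        with pytest.raises(ValueError):
            model(rng.random((1, 3, 64, 32)).astype(np.float32))  # non-square

    def test_bridges_off_preserves_output_contract(self, rng):
        model = build_model(ModelConfig(bridges=False, input_size=64), seed=0)
        out = model(rng.random((1, 3, 64, 64)).astype(np.float32))
        assert out.shape == (1, 1, 64, 64)

    def test_ablation_switches_replace_pvm_with_conv(self):
        conv_model = build_model(ModelConfig(encoder_pvm=False,
                                             decoder_pvm=False), seed=0)
        assert isinstance(conv_model.enc4, ConvBlock)
        assert conv_model.num_parameters() > 49_454  # convs are heavier

    def test_gradient_reaches_every_parameter(self, rng):
        model = build_model(ModelConfig(input_size=64), seed=0)
        x = rng.random((2, 3, 64, 64)).astype(np.float32)
        truth = (rng.random((2, 1, 64, 64)) > 0.6).astype(np.float32)
        loss = bce_dice_loss(model(x), truth)
        loss.backward()
        dead = [name for name, p in model.named_parameters()
                if p.grad is None or not np.any(p.grad)]
        assert dead == []
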