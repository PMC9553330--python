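"""Network building blocks: attention gate, pyramid pooling, recurrent-
residual atrous blocks, shape discipline, inference determinism."""

import numpy as np
import pytest

from ki67seg.exceptions import ConfigurationError, ShapeError
from ki67seg.nn import (
    AttentionGate,
    NetworkConfig,
    PyramidPool,
    RRAtrousBlock,
    Tensor,
    attention_gate,
    build_network,
    forward,
    load_checkpoint,
    predict_mask,
    save_checkpoint,
)


def selu(x):
    a, s = 1.6732632423543772, 1.0507009873554805
    return s * (x if x > 0 else a * (np.exp(x) - 1.0))


class TestAttentionGate:
    def test_zero_parameters_force_alpha_half(self, rng):
        gate = AttentionGate(4, 4, 2, rng=rng)
        gate.zero_parameters()
        x = Tensor(rng.standard_normal((1, 4, 8, 8)).astype(np.float32))
        g = Tensor(rng.standard_normal((1, 4, 8, 8)).astype(np.float32))
        alpha, x_out = attention_gate(x, g, gate)
        np.testing.assert_array_equal(alpha.data, 0.5)
        np.testing.assert_allclose(x_out.data, 0.5 * x.data + g.data, atol=1e-6)

    def test_scalar_case_matches_independent_arithmetic(self):
        # 1x1 grid, 1 channel, w_x=2, w_g=1, b_g=0, phi=1, b_phi=0, x=1, g=3
        gate = AttentionGate(1, 1, 1, rng=np.random.default_rng(0))
        gate.w_x.weight.data[...] = 2.0
        gate.w_g.weight.data[...] = 1.0
        gate.w_g.bias.data[...] = 0.0
        gate.phi.weight.data[...] = 1.0
        gate.phi.bias.data[...] = 0.0
        x = Tensor(np.full((1, 1, 1, 1), 1.0, np.float32))
        g = Tensor(np.full((1, 1, 1, 1), 3.0, np.float32))
        alpha, x_out = gate(x, g)
        # SeLU(5) = 1.0507... * 5 (positive branch carries the lambda scale),
        # so alpha = sigmoid(5.2535...) ~ 0.99480
        expected_alpha = 1.0 / (1.0 + np.exp(-selu(2 * 1 + 1 * 3)))
        assert alpha.data.item() == pytest.approx(expected_alpha, abs=1e-6)
        assert x_out.data.item() == pytest.approx(expected_alpha * 1.0 + 3.0, abs=1e-5)

    def test_alpha_strictly_inside_unit_interval(self, rng):
        gate = AttentionGate(3, 3, 2, rng=rng)
        for _ in range(20):
            x = Tensor(5 * rng.standard_normal((2, 3, 8, 8)).astype(np.float32))
            g = Tensor(5 * rng.standard_normal((2, 3, 8, 8)).astype(np.float32))
            alpha, _ = gate(x, g)
            assert alpha.data.min() > 0.0 and alpha.data.max() < 1.0

    def test_coarser_gating_signal_is_resampled(self, rng):
        gate = AttentionGate(3, 3, 2, rng=rng)
        x = Tensor(rng.standard_normal((1, 3, 8, 8)).astype(np.float32))
        g = Tensor(rng.standard_normal((1, 3, 4, 4)).astype(np.float32))
        alpha, x_out = gate(x, g)
        assert alpha.data.shape == (1, 1, 8, 8)
        assert x_out.data.shape == (1, 3, 8, 8)

    def test_channel_mismatch_rejected_for_additive_merge(self):
        with pytest.raises(ConfigurationError):
            AttentionGate(4, 8, 2, merge="add")


class TestPyramidPool:
    def test_output_channel_algebra(self, rng):
        pool = PyramidPool(32, (2, 4, 8, 16), reduce_channels=8, rng=rng)
        x = Tensor(rng.standard_normal((1, 32, 64, 64)).astype(np.float32))
        out = pool(x)
        assert out.data.shape == (1, 32 + 4 * 8, 64, 64)

    def test_constant_input_stays_constant(self, rng):
        pool = PyramidPool(2, (2, 4), reduce_channels=1, rng=rng)
        x = Tensor(np.full((1, 2, 16, 16), 3.0, np.float32))
        out = pool(x)
        for c in range(out.data.shape[1]):
            channel = out.data[0, c]
            np.testing.assert_allclose(channel, channel[0, 0], atol=1e-5)

    def test_scale2_branch_pools_block_means(self):
        # identity-like 1x1 map: weight 1, bias 0 on a single channel
        pool = PyramidPool(1, (2,), reduce_channels=1, rng=np.random.default_rng(0))
        pool.convs[0].weight.data[...] = 1.0
        pool.convs[0].bias.data[...] = 0.0
        x = np.arange(16, dtype=np.float32).reshape(1, 1, 4, 4)
        out = pool(Tensor(x)).data
        blocks = x[0, 0].reshape(2, 2, 2, 2).mean(axis=(1, 3))
        # at the upsampled corners the branch equals the pooled block mean
        branch = out[0, 1]
        for bi in range(2):
            for bj in range(2):
                np.testing.assert_allclose(
                    branch[3 * bi, 3 * bj], blocks[bi, bj], rtol=1e-6
                )

    def test_oversized_scale_rejected(self, rng):
        pool = PyramidPool(1, (16,), rng=rng)
        with pytest.raises(ConfigurationError):
            pool(Tensor(np.zeros((1, 1, 8, 8), np.float32)))


class TestRRAtrousBlock:
    def test_eval_mode_deterministic(self, rng):
        block = RRAtrousBlock(2, 4, rng=rng, drop_rng=np.random.default_rng(0))
        block.train(False)
        x = Tensor(rng.standard_normal((1, 2, 16, 16)).astype(np.float32))
        np.testing.assert_array_equal(block(x).data, block(x).data)

    def test_keep_prob_one_matches_eval(self, rng):
        block = RRAtrousBlock(2, 4, keep_prob=1.0, rng=rng,
                              drop_rng=np.random.default_rng(0))
        x = Tensor(rng.standard_normal((1, 2, 16, 16)).astype(np.float32))
        block.train(True)
        train_out = block(x).data
        block.train(False)
        np.testing.assert_array_equal(train_out, block(x).data)

    def test_zero_conv_weights_reduce_to_shortcut(self, rng):
        block = RRAtrousBlock(2, 4, rng=rng, drop_rng=np.random.default_rng(0))
        block.train(False)
        for conv in block.units:
            conv.weight.data[...] = 0.0
            conv.bias.data[...] = 0.0
        x = Tensor(rng.standard_normal((1, 2, 16, 16)).astype(np.float32))
        np.testing.assert_allclose(block(x).data, block.shortcut(x).data, atol=1e-6)

    def test_invalid_recurrence_rejected(self):
        with pytest.raises(ConfigurationError):
            RRAtrousBlock(2, 4, t=0)


class TestFullNetwork:
    @pytest.fixture(scope="class")
    def model(self):
        cfg = NetworkConfig(depth=2, in_channels=2, base_channels=4,
                            pyramid_scales=(2, 4))
        return build_network(cfg, seed=0)

    def test_probability_map_shape_and_range(self, model, rng):
        img = rng.standard_normal((2, 64, 64)).astype(np.float32)
        prob = forward(model, img)
        assert prob.shape == (64, 64)
        assert 0.0 < prob.min() and prob.max() < 1.0

    def test_indivisible_input_names_required_multiple(self, model, rng):
        with pytest.raises(ShapeError, match="multiple"):
            forward(model, rng.standard_normal((2, 50, 50)).astype(np.float32))

    def test_inference_bit_identical(self, model, rng):
        img = rng.standard_normal((2, 32, 32)).astype(np.float32)
        np.testing.assert_array_equal(forward(model, img), forward(model, img))

    def test_threshold_semantics(self, model, rng):
        img = rng.standard_normal((2, 32, 32)).astype(np.float32)
        prob = forward(model, img)
        np.testing.assert_array_equal(
            predict_mask(model, img, 0.5), (prob >= 0.5).astype(np.uint8)
        )
        with pytest.raises(Exception):
            predict_mask(model, img, 1.5)

    def test_raising_threshold_never_grows_mask(self, model, rng):
        img = rng.standard_normal((2, 32, 32)).astype(np.float32)
        masks = [predict_mask(model, img, t) for t in (0.3, 0.5, 0.7)]
        for lo, hi in zip(masks, masks[1:]):
            assert not (hi & ~lo).any()  # higher threshold is a subset

    def test_parameter_count_matches_layerwise_arithmetic(self, model):
        cfg = model.config

        def conv_params(cin, cout, k, bias=True):
            return cout * cin * k * k + (cout if bias else 0)

        def rr_params(cin, cout):
            return conv_params(cin, cout, 1) + len(cfg.dilation_rates) * conv_params(
                cout, cout, 3
            )

        chans = [cfg.base_channels * 2**i for i in range(cfg.depth)]
        c_bot = cfg.base_channels * 2**cfg.depth
        expected = 0
        cin = cfg.in_channels
        for c in chans:
            expected += rr_params(cin, c) + conv_params(c, c, 3)  # block + down
            cin = c
        expected += rr_params(cin, c_bot)
        reduce_c = max(1, c_bot // len(cfg.pyramid_scales))
        expected += len(cfg.pyramid_scales) * conv_params(c_bot, reduce_c, 1)
        cur = c_bot + len(cfg.pyramid_scales) * reduce_c
        for c in reversed(chans):
            expected += conv_params(cur, c, 1)  # upsample projection
            inter = max(1, c // 2)
            expected += (  # attention gate: w_x (no bias), w_g, phi
                conv_params(c, inter, 1, bias=False)
                + conv_params(c, inter, 1)
                + conv_params(inter, 1, 1)
            )
            expected += conv_params(c, c, 3)  # decoder conv
            cur = c
        expected += conv_params(cur, 1, 1)  # head
        assert model.n_params == expected

    def test_shape_trace_through_all_stages(self, model, rng):
        # encoder halves, decoder restores; walk a 64x64 input through
        from ki67seg.nn.autograd import Tensor as T

        x = T(rng.standard_normal((1, 2, 64, 64)).astype(np.float32))
        sizes = []
        for block, down in zip(model.enc_blocks, model.downs):
            x = block(x)
            sizes.append(x.shape[2:])
            x = down(x)
        assert sizes == [(64, 64), (32, 32)]
        assert x.shape[2:] == (16, 16)
        x = model.pyramid(model.bottleneck(x))
        assert x.shape[2:] == (16, 16)

    def test_checkpoint_round_trip(self, model, rng, tmp_path):
        img = rng.standard_normal((2, 32, 32)).astype(np.float32)
        before = forward(model, img)
        save_checkpoint(model, tmp_path / "m.npz")
        reloaded = load_checkpoint(tmp_path / "m.npz")
        np.testing.assert_array_equal(forward(reloaded, img), before)

    def test_config_validation(self):
        with pytest.raises(ConfigurationError):
            NetworkConfig(depth=0)
        with pytest.raises(ConfigurationError):
            NetworkConfig(pyramid_scales=(4, 2))
        with pytest.raises(ConfigurationError):
            NetworkConfig(out_threshold=1.5)
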