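"""Architecture contracts: shapes, residual identity, attention ranges,
parameter parity, receptive field, checkpoints."""

import numpy as np
import pytest
from conftest import random_config

from ricianet import (
    NetworkConfig,
    build_model,
    denoise,
    load_checkpoint,
    receptive_field,
    save_checkpoint,
)
from ricianet.layers import Conv2d
from ricianet.network import ChannelAttention, SpatialAttention


class TestConfig:
    def test_too_shallow_rejected(self):
        with pytest.raises(ValueError):
            NetworkConfig(n_extraction_layers=2)

    def test_even_attention_kernel_rejected(self):
        with pytest.raises(ValueError):
            NetworkConfig(spatial_attention_kernel=4)

    @pytest.mark.parametrize("bad", [{1}, {2}, {0}, {11}])
    def test_invalid_dilated_positions_rejected(self, bad):
        with pytest.raises(ValueError, match="dilated_layer_positions"):
            NetworkConfig(n_extraction_layers=10, dilated_layer_positions=frozenset(bad))

    def test_default_dilated_positions_skip_bn_free_layers(self):
        cfg = NetworkConfig(n_extraction_layers=10)
        assert cfg.dilated_positions == frozenset({4, 6, 8, 10})
        assert min(cfg.dilated_positions) >= 3

    def test_presets(self):
        tiny = NetworkConfig.tiny()
        assert tiny.base_channels == 16 and tiny.n_extraction_layers == 5
        assert NetworkConfig.from_preset("paper") == NetworkConfig()
        with pytest.raises(ValueError):
            NetworkConfig.from_preset("huge")


class TestShapes:
    def test_shape_preserved_for_random_configs(self, rng):
        for _ in range(10):
            cfg = random_config(rng)
            model = build_model(cfg, seed=0)
            h, w = int(rng.integers(8, 40)), int(rng.integers(8, 40))
            x = rng.random((1, 1, h, w)) * 255
            out = model.forward(x, training=False)
            assert out.shape == x.shape

    def test_batched_forward(self, micro_net_config, rng):
        model = build_model(micro_net_config, seed=0)
        x = rng.random((3, 1, 12, 10)) * 255
        assert model.forward(x, training=True).shape == x.shape

    def test_wrong_channel_count_rejected(self, micro_net_config, rng):
        model = build_model(micro_net_config, seed=0)
        with pytest.raises(ValueError, match="channel"):
            model.forward(rng.random((1, 2, 8, 8)))


class TestResidualContract:
    def test_zero_final_layer_is_identity(self, micro_net_config, small_phantom):
        model = build_model(micro_net_config, seed=3)
        model.final_conv.weight.data[...] = 0.0
        model.final_conv.bias.data[...] = 0.0
        result = denoise(model, small_phantom)
        assert not result.residual.any()
        np.testing.assert_array_equal(result.denoised, small_phantom)

    def test_denoised_is_noisy_minus_residual(self, micro_net_config, small_phantom, rng):
        model = build_model(micro_net_config, seed=4)
        noisy = small_phantom + rng.normal(0, 5, small_phantom.shape) ** 2
        result = denoise(model, noisy)
        # the clean estimate is defined by exact subtraction ...
        np.testing.assert_array_equal(result.denoised, noisy - result.residual)
        # ... so reconstruction holds to the last rounding step
        np.testing.assert_allclose(
            result.denoised + result.residual, noisy, rtol=0, atol=1e-12
        )

    def test_denoise_requires_2d(self, micro_net_config, rng):
        model = build_model(micro_net_config, seed=0)
        with pytest.raises(ValueError):
            denoise(model, rng.random((2, 8, 8)))


class TestAttention:
    def test_spatial_attention_map_in_open_unit_interval(self, rng):
        for pooling in ("max_extra", "avg_extra"):
            sa = SpatialAttention(kernel=7, pooling=pooling, rng=rng)
            x = rng.normal(size=(2, 6, 16, 14))
            out = sa.forward(x, training=False)
            assert out.shape == x.shape
            a = sa.last_attention_map
            assert np.all(a > 0) and np.all(a < 1)

    def test_spatial_attention_zero_input(self, rng):
        sa = SpatialAttention(kernel=3, pooling="max_extra", rng=rng)
        sa.conv.bias.data[:] = 0.7
        x = np.zeros((1, 4, 8, 8))
        out = sa.forward(x, training=False)
        # zero features pool to zero maps; the conv then outputs its bias
        expected = 1.0 / (1.0 + np.exp(-0.7))
        np.testing.assert_allclose(sa.last_attention_map, expected)
        assert not out.any()

    def test_unknown_pooling_rejected(self, rng):
        with pytest.raises(ValueError):
            SpatialAttention(kernel=3, pooling="median_extra", rng=rng)

    def test_channel_weights_in_open_unit_interval(self, rng):
        ca = ChannelAttention(channels=8, reduction=4, rng=rng)
        x = rng.normal(size=(2, 8, 10, 9))
        ca.forward(x, training=False)
        w = ca.last_weights
        assert w.shape == (2, 8)
        assert np.all(w > 0) and np.all(w < 1)

    def test_channel_attention_zero_input_gives_half_weights(self, rng):
        ca = ChannelAttention(channels=4, reduction=2, rng=rng)
        x = np.zeros((1, 4, 6, 6))
        out = ca.forward(x, training=False)
        np.testing.assert_allclose(ca.last_weights, 0.5)
        assert not out.any()

    def test_channel_attention_invariant_to_spatial_size(self, rng):
        # average and max of a constant map do not depend on its extent
        ca = ChannelAttention(channels=3, reduction=1, rng=rng)
        ca.forward(np.full((1, 3, 4, 4), 2.5), training=False)
        w_small = ca.last_weights.copy()
        ca.forward(np.full((1, 3, 8, 8), 2.5), training=False)
        np.testing.assert_allclose(ca.last_weights, w_small)


class TestParameterParity:
    def test_dilated_conv_same_parameter_count(self, rng):
        common = Conv2d(16, 16, kernel=3, dilation=1, rng=rng)
        dilated = Conv2d(16, 16, kernel=3, dilation=2, rng=rng)
        assert common.weight.data.shape == dilated.weight.data.shape
        n = lambda c: sum(p.data.size for p in c.params())
        assert n(common) == n(dilated)

    def test_model_count_independent_of_dilation(self):
        a = build_model(NetworkConfig.tiny(dilated_layer_positions=frozenset()), seed=0)
        b = build_model(
            NetworkConfig.tiny(dilated_layer_positions=frozenset({3, 4, 5})), seed=0
        )
        assert a.n_parameters() == b.n_parameters()


class TestReceptiveField:
    @pytest.mark.parametrize(
        "layers,expected",
        [
            ([(3, 1)], 3),
            ([(3, 2)], 5),  # one dilated 3x3 conv covers 5x5
            ([(3, 1), (3, 2)], 7),
            ([(3, 1)] * 2 + [(3, 2)] * 2, 13),
        ],
    )
    def test_recurrence(self, layers, expected):
        assert receptive_field(layers) == expected

    def test_from_config(self):
        cfg = NetworkConfig.tiny()  # 5 layers, dilation 2 at layer 4
        assert receptive_field(cfg) == 1 + 2 + 2 + 2 + 4 + 2

    def test_dilation_strictly_widens(self):
        cfg1 = NetworkConfig.tiny(dilated_layer_positions=frozenset())
        cfg2 = NetworkConfig.tiny(dilated_layer_positions=frozenset({3, 4, 5}))
        assert receptive_field(cfg2) > receptive_field(cfg1)


class TestGradientFlow:
    def test_every_parameter_receives_gradient(self, micro_net_config, rng):
        model = build_model(micro_net_config, seed=1)
        x = rng.random((2, 1, 12, 11)) * 255
        t = rng.normal(0, 20, x.shape)
        pred = model.forward(x, training=True)
        model.zero_grad()
        model.backward((pred - t) / x.shape[0])
        dead = [p.name for p in model.params() if not np.any(p.grad)]
        assert dead == []


class TestCheckpoint:
    def test_roundtrip_preserves_outputs(self, micro_net_config, rng, tmp_path):
        model = build_model(micro_net_config, seed=6)
        # give BN stats a nontrivial state
        x = rng.random((2, 1, 16, 14)) * 255
        model.forward(x, training=True)
        path = tmp_path / "model.ckpt.npz"
        save_checkpoint(model, path)
        clone = load_checkpoint(path)
        assert clone.config == model.config
        y = rng.random((1, 1, 20, 18)) * 255
        np.testing.assert_array_equal(
            clone.forward(y, training=False), model.forward(y, training=False)
        )
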