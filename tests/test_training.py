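"""Residual MSE loss, learning-rate schedule and the Adam training loop."""

import numpy as np
import pytest

from ricianet import (
    NetworkConfig,
    PhantomConfig,
    TrainConfig,
    build_model,
    generate_paired_dataset,
    lr_schedule,
    residual_mse_loss,
    train,
)


def brute_force_loss(pred, noisy, clean):
    """Direct elementwise transcription of the objective."""
    m = pred.shape[0]
    total = 0.0
    for k in range(m):
        desired = noisy[k] - clean[k]
        total += float(np.sum((pred[k] - desired) ** 2))
    return total / (2.0 * m)


class TestLoss:
    def test_perfect_prediction_is_zero(self, rng):
        noisy = rng.random((3, 8, 8)) * 255
        clean = rng.random((3, 8, 8)) * 255
        assert residual_mse_loss(noisy - clean, noisy, clean) == 0.0

    def test_constant_offset_closed_form(self, rng):
        # off by exactly 1 at every pixel of one P-pixel image -> P/2
        noisy = rng.random((1, 6, 7)) * 255
        clean = rng.random((1, 6, 7)) * 255
        pred = (noisy - clean) + 1.0
        assert residual_mse_loss(pred, noisy, clean) == pytest.approx(6 * 7 / 2.0)

    def test_zero_prediction_is_half_noise_energy(self, rng):
        clean = rng.random((4, 5, 5)) * 200
        noisy = clean + rng.normal(0, 10, clean.shape)
        expected = float(np.sum((noisy - clean) ** 2)) / (2 * 4)
        assert residual_mse_loss(np.zeros_like(clean), noisy, clean) == pytest.approx(
            expected
        )

    @pytest.mark.parametrize("m", [1, 3, 8])
    def test_matches_bruteforce_oracle(self, rng, m):
        pred = rng.normal(0, 30, (m, 9, 7))
        noisy = rng.random((m, 9, 7)) * 255
        clean = rng.random((m, 9, 7)) * 255
        ours = residual_mse_loss(pred, noisy, clean)
        ref = brute_force_loss(pred, noisy, clean)
        assert ours == pytest.approx(ref, rel=1e-10)
        assert ours >= 0

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            residual_mse_loss(np.zeros((2, 4, 4)), np.zeros((2, 4, 5)), np.zeros((2, 4, 5)))

    def test_empty_batch_rejected(self):
        z = np.zeros((0, 4, 4))
        with pytest.raises(ValueError):
            residual_mse_loss(z, z, z)


class TestSchedule:
    def test_paper_protocol_values(self):
        cfg = TrainConfig(epochs=40)
        assert lr_schedule(cfg, 0) == pytest.approx(1e-4)
        assert lr_schedule(cfg, 39) == pytest.approx(0.0000125)
        # multipliers scale the initial rate, not each other
        assert lr_schedule(cfg, 15) == pytest.approx(5e-5)
        assert lr_schedule(cfg, 25) == pytest.approx(2.5e-5)

    def test_single_stage_is_constant(self):
        cfg = TrainConfig(epochs=10, lr_multipliers=(1.0,))
        assert {lr_schedule(cfg, e) for e in range(10)} == {cfg.initial_lr}

    def test_explicit_boundaries(self):
        cfg = TrainConfig(
            epochs=10, lr_multipliers=(1.0, 0.5), lr_stage_boundaries=(4,)
        )
        assert lr_schedule(cfg, 3) == pytest.approx(1e-4)
        assert lr_schedule(cfg, 4) == pytest.approx(5e-5)

    def test_validation(self):
        with pytest.raises(ValueError):
            TrainConfig(epochs=10, lr_multipliers=(1.0, 0.5), lr_stage_boundaries=(2, 5))
        with pytest.raises(ValueError):
            TrainConfig(epochs=10, lr_multipliers=(0.5, 1.0))  # increasing
        with pytest.raises(ValueError):
            TrainConfig(epochs=0)
        with pytest.raises(ValueError):
            lr_schedule(TrainConfig(epochs=5), -1)


def micro_dataset(n=4, sigma=20.0, seed=0):
    cfg = PhantomConfig(height=24, width=20, n_tissue_regions=1, seed=seed)
    return generate_paired_dataset(n, [sigma], cfg, seed=seed)


def micro_model(seed=0):
    cfg = NetworkConfig(
        base_channels=4,
        n_extraction_layers=3,
        fusion_layers=1,
        spatial_attention_kernel=3,
        channel_attention_reduction=2,
    )
    return build_model(cfg, seed=seed)


class TestTrainLoop:
    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            train(micro_model(), [], TrainConfig(epochs=1))

    def test_identical_seeds_identical_histories(self):
        data = micro_dataset()
        cfg = TrainConfig(epochs=3, initial_lr=1e-3, batch_size=2, seed=5)
        _, h1 = train(micro_model(seed=2), data, cfg)
        _, h2 = train(micro_model(seed=2), data, cfg)
        assert h1 == h2

    def test_loss_decreases(self):
        data = micro_dataset(n=4)
        cfg = TrainConfig(epochs=20, initial_lr=2e-3, batch_size=2, seed=1)
        _, hist = train(micro_model(seed=1), data, cfg)
        losses = [h[2] for h in hist]
        assert losses[-1] < 0.5 * losses[0]

    def test_clean_data_zero_final_layer_stays_at_zero_loss(self):
        data = micro_dataset(sigma=0.0)
        model = micro_model()
        model.final_conv.weight.data[...] = 0.0
        model.final_conv.bias.data[...] = 0.0
        _, hist = train(model, data, TrainConfig(epochs=3, batch_size=2))
        assert all(h[2] == 0.0 for h in hist)

    def test_stage_callback_fires_once_per_stage(self):
        data = micro_dataset()
        calls = []
        cfg = TrainConfig(
            epochs=4,
            initial_lr=1e-3,
            lr_multipliers=(1.0, 0.5),
            lr_stage_boundaries=(2,),
            batch_size=2,
        )
        train(micro_model(), data, cfg, stage_callback=lambda s, e, m: calls.append((s, e)))
        assert calls == [(0, 0), (1, 2)]

    def test_history_records_schedule(self):
        data = micro_dataset()
        cfg = TrainConfig(epochs=4, initial_lr=1e-3, batch_size=4)
        _, hist = train(micro_model(), data, cfg)
        assert [h[0] for h in hist] == [0, 1, 2, 3]
        assert [h[1] for h in hist] == [1e-3, 5e-4, 2.5e-4, 1.25e-4]

    def test_final_stage_improves_on_first_across_seeds(self):
        # smoke property: staged training ends better than it starts
        # for at least 9 of 10 seeds on a fixed micro dataset
        data = micro_dataset(n=4, seed=3)
        wins = 0
        for seed in range(10):
            cfg = TrainConfig(epochs=8, initial_lr=1e-3, batch_size=2, seed=seed)
            _, hist = train(micro_model(seed=seed), data, cfg)
            if hist[-1][2] <= hist[0][2]:
                wins += 1
        assert wins >= 9
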