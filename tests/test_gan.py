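"""Conditional-GAN contracts: builders, losses, buffer, training loop."""

import numpy as np
import pytest

from sfdigan.dataset import generate_samples
from sfdigan.gan import (DiscriminatorSpec, GeneratorSpec, HistoryBuffer,
                         TrainConfig, adversarial_loss, build_discriminator,
                         build_generator, l1_loss, learning_rate,
                         load_checkpoint, predict, save_checkpoint,
                         total_generator_loss, train)
from sfdigan.scenes import ConfigError, rectangular_model


def tiny_config(epochs=4, seed=0, size=32):
    return TrainConfig(
        epochs=epochs, batch_size=4, seed=seed,
        generator=GeneratorSpec(size=size, base_channels=8),
        discriminator=DiscriminatorSpec(size=size, base_channels=8))


@pytest.fixture(scope="module")
def tiny_samples(calib):
    scenes = rectangular_model(n_frames=12, seed=0)
    return generate_samples(scenes, calib, resolution=32)


class TestBuilders:
    def test_generator_shape_contract(self):
        gen = build_generator(GeneratorSpec(size=64, base_channels=8), seed=0)
        x = np.zeros((2, 3, 64, 64), np.float32)
        out = gen.forward(x, train=False)
        assert out.shape == (2, 3, 64, 64)

    def test_discriminator_patch_scores(self):
        disc = build_discriminator(DiscriminatorSpec(size=64, base_channels=8), seed=0)
        xy = np.zeros((2, 6, 64, 64), np.float32)
        scores = disc.forward(xy, train=False)
        assert scores.shape[:2] == (2, 1)
        assert np.all(np.isfinite(scores))

    def test_same_seed_identical_weights(self):
        a = build_generator(GeneratorSpec(size=32, base_channels=8), seed=9)
        b = build_generator(GeneratorSpec(size=32, base_channels=8), seed=9)
        for pa, pb in zip(a.params(), b.params()):
            np.testing.assert_array_equal(pa.data, pb.data)

    def test_init_statistics_match_prescription(self):
        gen = build_generator(GeneratorSpec(size=64, base_channels=16), seed=3)
        weights = np.concatenate([p.data.ravel() for p in gen.params()
                                  if p.data.ndim == 2])
        assert abs(weights.mean()) < 0.002
        assert weights.std() == pytest.approx(0.02, rel=0.1)

    def test_non_power_of_two_rejected(self):
        with pytest.raises(ConfigError):
            GeneratorSpec(size=48)
        with pytest.raises(ConfigError):
            DiscriminatorSpec(size=24)


class TestLosses:
    def test_perfect_discriminator_zero_loss(self):
        assert adversarial_loss(np.ones((2, 1, 4, 4)), np.zeros((2, 1, 4, 4)),
                                "discriminator") == 0.0

    def test_perfect_fooling_zero_generator_loss(self):
        assert adversarial_loss(None, np.ones((2, 1, 4, 4)), "generator") == 0.0

    def test_half_scores_give_half_loss(self):
        half = np.full((1, 1, 2, 2), 0.5)
        assert adversarial_loss(half, half, "discriminator") == pytest.approx(0.5)

    def test_l1_examples(self):
        a = np.zeros((2, 2))
        assert l1_loss(a, a) == 0.0
        assert l1_loss(a, a + 0.3) == pytest.approx(0.3)
        diffs = np.array([[0.0, 0.1], [0.2, 0.1]])
        assert l1_loss(np.zeros_like(diffs), diffs) == pytest.approx(0.1)

    def test_l1_shape_mismatch(self):
        with pytest.raises(ValueError):
            l1_loss(np.zeros((2, 2)), np.zeros((3, 3)))

    def test_total_loss_combination(self):
        assert total_generator_loss(0.5, 0.01, 60.0) == pytest.approx(1.1)
        assert total_generator_loss(0.7, 0.5, 0.0) == pytest.approx(0.7)
        assert total_generator_loss(0.7, 0.0, 60.0) == pytest.approx(0.7)


class TestSchedule:
    def test_constant_then_linear_decay(self):
        cfg = tiny_config(epochs=100)
        assert learning_rate(1, cfg) == pytest.approx(1e-4)
        assert learning_rate(50, cfg) == pytest.approx(1e-4)
        assert learning_rate(75, cfg) == pytest.approx(0.5e-4)
        assert learning_rate(100, cfg) == pytest.approx(0.0)

    def test_odd_epoch_count_rejected(self):
        with pytest.raises(ConfigError):
            tiny_config(epochs=5)


class TestHistoryBuffer:
    def test_capacity_never_exceeded(self):
        buf = HistoryBuffer(capacity=64, seed=0)
        x = np.zeros((10, 3, 4, 4), np.float32)
        for _ in range(10):
            buf.push(x, x)
        assert len(buf) == 64

    def test_sampling_uniform_over_contents(self):
        buf = HistoryBuffer(capacity=8, seed=1)
        for i in range(8):
            buf.push(np.full((1, 1, 1, 1), float(i)), np.zeros((1, 1, 1, 1)))
        xs, _ = buf.sample(4000)
        counts = np.bincount(xs.ravel().astype(int), minlength=8)
        assert counts.min() > 350  # each of the 8 entries drawn ~500 times

    def test_seeded_reproducibility(self):
        out = []
        for _ in range(2):
            buf = HistoryBuffer(capacity=4, seed=5)
            for i in range(9):
                buf.push(np.full((1, 1, 1, 1), float(i)), np.zeros((1, 1, 1, 1)))
            xs, _ = buf.sample(6)
            out.append(xs.ravel().tolist())
        assert out[0] == out[1]


class TestTraining:
    def test_loss_history_reproducible(self, tiny_samples):
        h1 = train(tiny_samples[:8], tiny_samples[8:], tiny_config(epochs=2, seed=4))[1]
        h2 = train(tiny_samples[:8], tiny_samples[8:], tiny_config(epochs=2, seed=4))[1]
        np.testing.assert_allclose(h1["g_l1"], h2["g_l1"], rtol=1e-6)
        np.testing.assert_allclose(h1["val_l1"], h2["val_l1"], rtol=1e-6)

    def test_history_columns_and_lr_schedule_applied(self, tiny_samples):
        _, hist = train(tiny_samples[:8], tiny_samples[8:], tiny_config(epochs=4))
        assert list(hist["epoch"]) == [1, 2, 3, 4]
        assert hist["lr"].iloc[1] == pytest.approx(1e-4)
        assert hist["lr"].iloc[-1] == pytest.approx(0.0)
        assert {"d_loss", "g_adv", "g_l1", "val_l1", "val_mse"} <= set(hist.columns)

    def test_empty_training_split_rejected(self, tiny_samples):
        with pytest.raises(ConfigError):
            train([], tiny_samples, tiny_config(epochs=2))

    def test_discriminator_spectral_norms_near_unity_after_training(self, tiny_samples):
        from sfdigan.nn import SpectralNorm

        cfg = tiny_config(epochs=2, seed=1)
        # train() rebuilds its own discriminator; rebuild identically and
        # check the invariant on a forward pass of real data instead
        from sfdigan.gan import build_discriminator, samples_to_arrays
        disc = build_discriminator(cfg.discriminator, seed=cfg.seed + 1)
        x, y = samples_to_arrays(tiny_samples[:4])
        for _ in range(25):
            disc.forward(np.concatenate([x, y], axis=1), train=True)
        for layer in disc.layers:
            if isinstance(layer, SpectralNorm):
                assert layer.spectral_sigma() == pytest.approx(1.0, abs=0.05)


class TestPredict:
    def test_shape_and_determinism(self, tiny_samples):
        gen, _ = train(tiny_samples[:8], tiny_samples[8:], tiny_config(epochs=2))
        out1 = predict(gen, tiny_samples[0].input_half)
        out2 = predict(gen, tiny_samples[0].input_half)
        assert out1.shape == tiny_samples[0].input_half.shape
        assert out1.dtype == np.uint8
        np.testing.assert_array_equal(out1, out2)

    def test_size_mismatch_rejected(self, tiny_samples):
        gen = build_generator(GeneratorSpec(size=64, base_channels=8))
        with pytest.raises(ValueError):
            predict(gen, tiny_samples[0].input_half)  # 32 px input

    def test_checkpoint_round_trip(self, tiny_samples, tmp_path):
        gen, _ = train(tiny_samples[:8], tiny_samples[8:], tiny_config(epochs=2))
        path = tmp_path / "gen.npz"
        save_checkpoint(gen, path, tiny_config(epochs=2))
        back = load_checkpoint(path)
        np.testing.assert_array_equal(predict(gen, tiny_samples[0].input_half),
                                      predict(back, tiny_samples[0].input_half))
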