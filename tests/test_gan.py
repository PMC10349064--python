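import numpy as np
import pytest

from pxafkit.ecg_synth import synth_dataset
from pxafkit.gan import (Discriminator, GANConfig, Generator,
                         discriminator_forward, gan_loss, gan_sample,
                         gan_train, generator_forward, load_checkpoint,
                         save_checkpoint)
from pxafkit.types import InvalidParameterError


@pytest.fixture(scope="module")
def desk_cfg():
    return GANConfig(noise_shape=(2, 512), epochs=0, seed=0)


@pytest.fixture(scope="module")
def generator(desk_cfg):
    return Generator(desk_cfg, np.random.default_rng(0))


class TestGeneratorShapes:
    def test_output_matches_input_shape(self, generator, rng):
        z = rng.standard_normal((2, 512))
        assert generator_forward(generator, z).shape == (2, 512)

    def test_batch_shapes(self, generator, rng):
        z = rng.standard_normal((3, 2, 512))
        assert generator_forward(generator, z).shape == (3, 2, 512)

    def test_indivisible_length_rejected_without_padding(self):
        with pytest.raises(InvalidParameterError):
            GANConfig(noise_shape=(2, 5000))

    def test_5000_with_padding(self):
        cfg = GANConfig(noise_shape=(2, 5000), pad_to_multiple=True,
                        base_width=4)
        gen = Generator(cfg, np.random.default_rng(0))
        z = np.random.default_rng(1).standard_normal((2, 5000))
        assert generator_forward(gen, z).shape == (2, 5000)

    def test_deterministic(self, generator, rng):
        z = rng.standard_normal((2, 512))
        a = generator_forward(generator, z)
        b = generator_forward(generator, z)
        assert np.array_equal(a, b)

    def test_output_bounded(self, generator, rng):
        out = generator_forward(generator, rng.standard_normal((2, 512)))
        assert np.abs(out).max() <= generator.cfg.amp_mv


class TestDiscriminator:
    def test_scalar_score(self, desk_cfg, rng):
        disc = Discriminator(desk_cfg, np.random.default_rng(1))
        score = discriminator_forward(disc, rng.standard_normal((2, 512)))
        assert np.isfinite(score)

    def test_zero_phase_shuffle_deterministic(self, rng):
        cfg = GANConfig(noise_shape=(2, 512), phase_shuffle_n=0)
        disc = Discriminator(cfg, np.random.default_rng(1))
        x = rng.standard_normal((2, 512))
        assert discriminator_forward(disc, x) == \
            discriminator_forward(disc, x)

    def test_shape_mismatch_rejected(self, desk_cfg, rng):
        disc = Discriminator(desk_cfg, np.random.default_rng(1))
        with pytest.raises(InvalidParameterError):
            discriminator_forward(disc, rng.standard_normal((2, 256)))


class TestGanLoss:
    def test_perfect_discriminator_limit(self):
        terms = gan_loss(np.full(4, 100.0), np.full(4, -100.0))
        assert terms.d_loss == pytest.approx(0.0, abs=1e-5)

    def test_undecided_discriminator_closed_form(self):
        terms = gan_loss(np.zeros(5), np.zeros(5))
        assert terms.d_loss == pytest.approx(2 * np.log(2))
        assert terms.g_loss == pytest.approx(np.log(2))

    def test_generator_loss_monotone_in_fake_scores(self):
        lo = gan_loss(np.zeros(3), np.full(3, -1.0)).g_loss
        hi = gan_loss(np.zeros(3), np.full(3, 1.0)).g_loss
        assert hi < lo

    def test_saturating_objective(self):
        terms = gan_loss(np.zeros(3), np.zeros(3),
                         generator_objective="saturating")
        assert terms.g_loss == pytest.approx(np.log(0.5))


@pytest.fixture(scope="module")
def real_segments():
    return synth_dataset(0, 24, 4.0, seed=3)


class TestTraining:

    def test_zero_epochs_returns_initialized(self, real_segments):
        gen, disc, hist = gan_train(real_segments,
                                    GANConfig(epochs=0, seed=0))
        assert hist == {"d_loss": [], "g_loss": []}

    def test_short_run_losses_finite(self, real_segments):
        _, _, hist = gan_train(real_segments,
                               GANConfig(epochs=2, seed=0, batch_size=12))
        assert len(hist["d_loss"]) == 2
        assert np.isfinite(hist["d_loss"]).all()
        assert np.isfinite(hist["g_loss"]).all()

    def test_same_seed_identical_history(self, real_segments):
        cfg = GANConfig(epochs=1, seed=4, batch_size=12)
        _, _, h1 = gan_train(real_segments, cfg)
        _, _, h2 = gan_train(real_segments, cfg)
        assert h1 == h2

    def test_empty_input_rejected(self):
        with pytest.raises(InvalidParameterError):
            gan_train([], GANConfig(epochs=1))


class TestSampling:
    def test_sample_count_shape_label(self, generator):
        segs = gan_sample(generator, 4, seed=2)
        assert len(segs) == 4
        assert all(s.signals.shape == (2, 512) for s in segs)
        assert all(s.label == "pxaf" for s in segs)

    def test_zero_samples(self, generator):
        assert gan_sample(generator, 0) == []

    def test_checkpoint_round_trip(self, tmp_path, desk_cfg):
        rng = np.random.default_rng(5)
        gen, disc = Generator(desk_cfg, rng), Discriminator(desk_cfg, rng)
        path = save_checkpoint(gen, disc, tmp_path / "ck.npz")
        rng2 = np.random.default_rng(99)
        gen2, disc2 = Generator(desk_cfg, rng2), Discriminator(desk_cfg, rng2)
        load_checkpoint(gen2, disc2, path)
        z = np.random.default_rng(1).standard_normal((2, 512))
        assert np.array_equal(generator_forward(gen, z),
                              generator_forward(gen2, z))
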