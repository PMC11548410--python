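"""Spectral loss, minibatch discrimination, filter and GAN mechanics."""

import numpy as np
import pytest

from kinegan import lowpass_2hz, minibatch_features, spectral_loss
from kinegan.gan import SpectralCGAN, _SpectralGrad

from conftest import TOY_GAN_PARAMS, make_toy_sinusoids


def naive_dft_magnitude(x):
    """O(n^2) DFT-by-summation magnitude spectrum of a 1-D signal."""
    n = len(x)
    bins = n // 2 + 1
    mags = np.empty(bins)
    for k in range(bins):
        re = sum(x[t] * np.cos(2 * np.pi * k * t / n) for t in range(n))
        im = sum(-x[t] * np.sin(2 * np.pi * k * t / n) for t in range(n))
        mags[k] = np.sqrt(re**2 + im**2)
    return mags


class TestSpectralLoss:
    def test_zero_on_identical_batches(self):
        x = np.random.default_rng(0).normal(size=(4, 32, 3))
        assert spectral_loss(x, x) == 0.0

    def test_invariant_to_circular_shift(self):
        a = np.zeros((1, 8))
        b = np.zeros((1, 8))
        a[0, 0] = 1.0
        b[0, 1] = 1.0
        assert spectral_loss(a, b) == pytest.approx(0.0, abs=1e-25)

    @pytest.mark.parametrize("mode", ["batch_mean", "paired"])
    def test_matches_naive_dft_oracle(self, mode):
        rng = np.random.default_rng(5)
        real = rng.normal(size=(3, 12, 2))
        fake = rng.normal(size=(3, 12, 2))
        mag_r = np.stack([[naive_dft_magnitude(real[i, :, c]) for c in range(2)]
                          for i in range(3)]).transpose(0, 2, 1)
        mag_f = np.stack([[naive_dft_magnitude(fake[i, :, c]) for c in range(2)]
                          for i in range(3)]).transpose(0, 2, 1)
        if mode == "batch_mean":
            expected = np.mean((mag_r.mean(axis=0) - mag_f.mean(axis=0)) ** 2)
        else:
            expected = np.mean((mag_r - mag_f) ** 2)
        assert spectral_loss(real, fake, mode) == pytest.approx(expected, abs=1e-10)

    def test_symmetric_and_nonnegative_and_reorder_invariant(self):
        rng = np.random.default_rng(6)
        a = rng.normal(size=(5, 16, 2))
        b = rng.normal(size=(5, 16, 2))
        assert spectral_loss(a, b) >= 0
        assert spectral_loss(a, b) == pytest.approx(spectral_loss(b, a), rel=1e-12)
        perm = rng.permutation(5)
        assert spectral_loss(a, b) == pytest.approx(spectral_loss(a[perm], b), rel=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            spectral_loss(np.zeros((2, 8, 1)), np.zeros((2, 9, 1)))

    def test_gradient_helper_agrees_with_fft_value(self):
        rng = np.random.default_rng(7)
        real = rng.normal(size=(3, 20, 2))
        fake = rng.normal(size=(3, 20, 2))
        helper = _SpectralGrad(20)
        for mode in ("batch_mean", "paired"):
            loss, grad = helper.loss_and_grad(real, fake, mode)
            assert loss == pytest.approx(spectral_loss(real, fake, mode), rel=1e-12)
            idx = (1, 7, 0)
            eps = 1e-6
            fp, fm = fake.copy(), fake.copy()
            fp[idx] += eps
            fm[idx] -= eps
            num = (spectral_loss(real, fp, mode) - spectral_loss(real, fm, mode)) / (2 * eps)
            assert grad[idx] == pytest.approx(num, abs=1e-7)


class TestMinibatchFeatures:
    def test_single_sample_gives_zeros(self):
        f = np.random.default_rng(0).normal(size=(1, 4))
        T = np.random.default_rng(1).normal(size=(4, 3, 2))
        assert np.array_equal(minibatch_features(f, T), np.zeros((1, 3)))

    def test_two_identical_rows_give_unit_features(self):
        f = np.tile(np.random.default_rng(2).normal(size=(1, 4)), (2, 1))
        T = np.random.default_rng(3).normal(size=(4, 3, 2))
        assert np.allclose(minibatch_features(f, T), 1.0)  # exp(-0) summed over 1 other sample

    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(4)
        f = rng.normal(size=(3, 5))
        T = rng.normal(size=(5, 2, 3))
        expected = np.zeros((3, 2))
        for i in range(3):
            for b in range(2):
                for j in range(3):
                    if j != i:
                        mi = f[i] @ T[:, b, :]
                        mj = f[j] @ T[:, b, :]
                        expected[i, b] += np.exp(-np.abs(mi - mj).sum())
        assert np.allclose(minibatch_features(f, T), expected, atol=1e-10)

    def test_collapsed_batch_scores_higher_than_diverse(self):
        """A batch of identical samples yields larger similarity features
        than a diverse batch: the discriminator can see mode collapse."""
        rng = np.random.default_rng(5)
        T = rng.normal(size=(6, 4, 3))
        collapsed = np.tile(rng.normal(size=(1, 6)), (8, 1))
        diverse = rng.normal(size=(8, 6)) * 3
        assert minibatch_features(collapsed, T).mean() > minibatch_features(diverse, T).mean()


class TestLowpass:
    def test_dc_preserved(self):
        x = np.full((300, 9), 3.7)
        assert np.allclose(lowpass_2hz(x), x, atol=1e-9)

    def test_passband_sine_preserved(self):
        t = np.arange(300) / 60.0
        x = np.sin(2 * np.pi * 0.5 * t)[:, None]
        out = lowpass_2hz(x)
        mid = slice(60, 240)  # avoid edge transients
        assert np.abs(out[mid, 0]).max() == pytest.approx(1.0, rel=0.02)

    def test_stopband_sine_attenuated_20db(self):
        t = np.arange(300) / 60.0
        x = np.sin(2 * np.pi * 5.0 * t)[:, None]
        out = lowpass_2hz(x)
        assert np.abs(out[60:240, 0]).max() < 0.1  # >= 20 dB down

    def test_idempotent_in_passband(self):
        t = np.arange(300) / 60.0
        x = np.sin(2 * np.pi * 0.5 * t)[:, None]
        once = lowpass_2hz(x)
        twice = lowpass_2hz(once)
        mid = slice(60, 240)
        extra = np.abs(twice[mid] - once[mid]).max() / np.abs(once[mid]).max()
        assert extra < 0.01

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError):
            lowpass_2hz(np.zeros((10, 9)))


@pytest.fixture(scope="module")
def toy_gan():
    """Briefly trained toy GAN shared by the mechanics tests."""
    x, y = make_toy_sinusoids(0, n_per_class=32)
    gan = SpectralCGAN(epochs=3, random_state=0, **TOY_GAN_PARAMS)
    return gan.fit(x, y)


class TestGanMechanics:
    def test_loss_history_bookkeeping(self, toy_gan):
        assert len(toy_gan.loss_history_) == 3
        assert np.isfinite(toy_gan.loss_history_[["d_loss", "g_adversarial", "g_spectral"]]).all().all()

    def test_generator_output_shape_and_determinism(self, toy_gan):
        z = np.random.default_rng(1).standard_normal((4, toy_gan.noise_dim))
        a = toy_gan.generator_forward(z, np.zeros(4, dtype=int))
        b = toy_gan.generator_forward(z, np.zeros(4, dtype=int))
        assert a.shape == (4, 64, 1)
        assert np.all(np.isfinite(a))
        assert np.array_equal(a, b)

    def test_label_pathway_is_live(self, toy_gan):
        z = np.random.default_rng(2).standard_normal((1, toy_gan.noise_dim))
        a = toy_gan.generator_forward(z, [0])
        b = toy_gan.generator_forward(z, [1])
        assert not np.allclose(a, b)

    def test_sample_reproducible_and_destandardized(self, toy_gan):
        a = toy_gan.sample(0, 3, rng=np.random.default_rng(9))
        b = toy_gan.sample(0, 3, rng=np.random.default_rng(9))
        assert np.array_equal(a, b)
        restd = toy_gan.standardize(a)
        z = np.random.default_rng(9).standard_normal((3, toy_gan.noise_dim))
        raw = toy_gan.generator_forward(z, np.zeros(3, dtype=int))
        assert np.allclose(restd, raw, atol=1e-6)

    def test_unknown_label_rejected(self, toy_gan):
        with pytest.raises(ValueError):
            toy_gan.sample(5, 2)

    def test_save_load_round_trip(self, toy_gan, tmp_path):
        toy_gan.save(tmp_path / "bundle")
        loaded = SpectralCGAN.load(tmp_path / "bundle")
        z = np.random.default_rng(3).standard_normal((2, toy_gan.noise_dim))
        assert np.allclose(
            toy_gan.generator_forward(z, [0, 1]), loaded.generator_forward(z, [0, 1])
        )
        assert np.array_equal(loaded.classes_, toy_gan.classes_)

    def test_training_reproducible_given_seed(self):
        x, y = make_toy_sinusoids(0, n_per_class=16)
        runs = []
        for _ in range(2):
            gan = SpectralCGAN(epochs=2, random_state=11, **TOY_GAN_PARAMS)
            gan.fit(x, y)
            runs.append(gan.sample(0, 2, rng=np.random.default_rng(0)))
        assert np.array_equal(runs[0], runs[1])
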