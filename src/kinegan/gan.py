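"""Conditional GAN with an FFT spectral loss for class-conditioned trial synthesis.

The generator maps (noise vector, class label) to a 300x9 trial in
standardized units: the concatenated input passes through a dense layer
with batch normalization, ReLU and dropout, is reshaped to a short
multi-channel sequence, and is refined by two upsampling blocks
(upsampling + Conv1D with 256 then 128 filters, kernel 15, each with batch
norm / ReLU / dropout); the length is adjusted to 300 by zero-padding or
cropping and a final 9-filter Conv1D produces the channels. The
discriminator mirrors the generator with two strided convolution blocks
(LeakyReLU 0.2, dropout) and a minibatch-discrimination feature block
before the real/synthetic output, and receives the class label broadcast
as extra input channels.

Both networks train adversarially with binary cross-entropy under Adam
(learning rate 0.0003, beta1 0.5). The generator additionally minimizes a
spectral loss — the squared difference between the magnitude FFT spectra of
real and generated batches — which suppresses the spurious energy above
2 Hz that a plain conditional GAN produces on smooth kinematic signals. A
zero-phase 2 Hz Butterworth lowpass is available for generated output.

Channels are standardized to zero mean / unit variance over the training
set before GAN training (mixed cm/rad scales would otherwise dominate the
losses); the inverse transform is applied when sampling.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt
from sklearn.base import BaseEstimator

from .channels import GROUPS, N_CHANNELS, SAMPLE_RATE_HZ, TASKS, TRIAL_LENGTH
from .nn import (
    Adam,
    BatchNorm,
    Conv1D,
    Dense,
    Dropout,
    Embedding,
    Flatten,
    LeakyReLU,
    MinibatchDiscrimination,
    ReLU,
    Reshape,
    Sequential,
    UpSample1D,
    sigmoid_bce_with_logits,
)
from .nn.layers import Layer
from .trials import Dataset, KinematicTrial, decode_class


# ---------------------------------------------------------------------------
# functional pieces


def spectral_loss(real_batch: np.ndarray, fake_batch: np.ndarray, mode: str = "batch_mean") -> float:
    """Squared difference between FFT magnitude spectra of two batches.

    In ``batch_mean`` mode (default) the magnitude spectra of individual
    samples are averaged over the batch separately for real and fake, and
    the mean squared difference of the two batch-mean spectra is returned
    (mean over channels and frequency bins). ``paired`` mode compares
    spectra sample-by-sample in batch order. Zero iff the compared spectra
    are identical; invariant to circular time shifts of any sample.
    """
    real = np.asarray(real_batch, dtype=float)
    fake = np.asarray(fake_batch, dtype=float)
    if real.shape != fake.shape:
        raise ValueError(f"batch shapes differ: {real.shape} vs {fake.shape}")
    if real.ndim == 2:
        real = real[:, :, None]
        fake = fake[:, :, None]
    if real.ndim != 3 or real.shape[0] < 1:
        raise ValueError("expected (B, L) or (B, L, C) batches with B >= 1")
    mag_r = np.abs(np.fft.rfft(real, axis=1))
    mag_f = np.abs(np.fft.rfft(fake, axis=1))
    if mode == "batch_mean":
        return float(np.mean((mag_r.mean(axis=0) - mag_f.mean(axis=0)) ** 2))
    if mode == "paired":
        return float(np.mean((mag_r - mag_f) ** 2))
    raise ValueError(f"unknown spectral loss mode {mode!r}")


def minibatch_features(f: np.ndarray, T: np.ndarray) -> np.ndarray:
    """Minibatch-discrimination features.

    ``f`` is a (B, A) feature matrix, ``T`` an (A, B', C) projection tensor.
    Row i is projected to M_i = f_i . T of shape (B', C) and the b-th output
    feature of sample i is sum_{j != i} exp(-||M_{i,b} - M_{j,b}||_1). For
    B = 1 the sum is empty and all features are zero.
    """
    f = np.asarray(f, dtype=float)
    T = np.asarray(T, dtype=float)
    if f.ndim != 2 or T.ndim != 3 or T.shape[0] != f.shape[1]:
        raise ValueError("f must be (B, A) and T (A, B', C)")
    b = f.shape[0]
    m = np.tensordot(f, T, axes=(1, 0))  # (B, B', C)
    l1 = np.abs(m[:, None, :, :] - m[None, :, :, :]).sum(axis=-1)  # (B, B, B')
    expneg = np.exp(-l1)
    expneg[np.eye(b, dtype=bool)] = 0.0
    return expneg.sum(axis=1)


def lowpass_2hz(batch: np.ndarray, cutoff_hz: float = 2.0, fs: float = SAMPLE_RATE_HZ) -> np.ndarray:
    """Zero-phase 4th-order Butterworth lowpass along the time axis.

    Accepts (L, C) or (B, L, C); shape is preserved. Forward-backward
    filtering doubles the effective order, so the -3 dB point sits slightly
    below the nominal cutoff and the phase is exactly zero.
    """
    if fs <= 2 * cutoff_hz:
        raise ValueError("sample rate must exceed twice the cutoff")
    batch = np.asarray(batch, dtype=float)
    axis = 0 if batch.ndim == 2 else 1
    b, a = butter(4, cutoff_hz, btype="low", fs=fs)
    padlen = 3 * max(len(a), len(b))
    if batch.shape[axis] <= padlen:
        raise ValueError(f"signal length {batch.shape[axis]} too short for filter padding ({padlen})")
    return filtfilt(b, a, batch, axis=axis)


class _SpectralGrad:
    """Spectral loss with analytic gradient w.r.t. the fake batch.

    Implements the magnitude spectrum as explicit cosine/sine projections so
    the backward pass is plain matrix calculus; values agree with the
    rfft-based :func:`spectral_loss` to floating-point precision.
    """

    def __init__(self, length: int) -> None:
        t = np.arange(length)
        k = np.arange(length // 2 + 1)
        ang = 2 * np.pi * np.outer(t, k) / length
        self.C = np.cos(ang)  # (L, K)
        self.S = -np.sin(ang)

    @staticmethod
    def _project(x: np.ndarray, basis: np.ndarray) -> np.ndarray:
        # (B, L, C) x (L, K) -> (B, K, C) through a BLAS tensordot
        return np.tensordot(x, basis, axes=(1, 0)).transpose(0, 2, 1)

    def loss_and_grad(self, real: np.ndarray, fake: np.ndarray, mode: str = "batch_mean"):
        re_r = self._project(real, self.C)
        im_r = self._project(real, self.S)
        mag_r = np.sqrt(re_r**2 + im_r**2)
        re_f = self._project(fake, self.C)
        im_f = self._project(fake, self.S)
        mag_f = np.sqrt(re_f**2 + im_f**2)
        b, kk, cc = mag_f.shape
        if mode == "batch_mean":
            diff = mag_f.mean(axis=0) - mag_r.mean(axis=0)  # (K, C)
            loss = float(np.mean(diff**2))
            dmag_f = np.broadcast_to(2 * diff / (kk * cc * b), mag_f.shape)
        elif mode == "paired":
            diff = mag_f - mag_r
            loss = float(np.mean(diff**2))
            dmag_f = 2 * diff / (b * kk * cc)
        else:
            raise ValueError(f"unknown spectral loss mode {mode!r}")
        safe = np.where(mag_f > 0, mag_f, 1.0)
        dre = dmag_f * re_f / safe
        dim = dmag_f * im_f / safe
        grad = np.tensordot(dre, self.C, axes=(1, 1)).transpose(0, 2, 1) + np.tensordot(
            dim, self.S, axes=(1, 1)
        ).transpose(0, 2, 1)
        return loss, grad


class _AdjustLength(Layer):
    """Zero-pad or crop the time axis to a target length."""

    def __init__(self, target: int) -> None:
        super().__init__()
        self.target = target

    def forward(self, x, training=True):
        self._length = x.shape[1]
        if self._length >= self.target:
            return x[:, : self.target, :]
        pad = self.target - self._length
        return np.pad(x, ((0, 0), (0, pad), (0, 0)))

    def backward(self, grad):
        if self._length >= self.target:
            if self._length == self.target:
                return grad
            pad = self._length - self.target
            return np.pad(grad, ((0, 0), (0, pad), (0, 0)))
        return grad[:, : self._length, :]


# ---------------------------------------------------------------------------
# generator / discriminator wiring


class _Generator:
    def __init__(self, cfg: "SpectralCGAN", n_classes: int, rng: np.random.Generator) -> None:
        self.noise_dim = cfg.noise_dim
        self.embed = Embedding(n_classes, cfg.embed_dim, rng)
        l0, c0 = cfg.reshape_length, cfg.reshape_channels
        f1, f2 = cfg.block_filters
        k = cfg.kernel_size
        self.net = Sequential(
            [
                Dense(cfg.noise_dim + cfg.embed_dim, l0 * c0, rng),
                BatchNorm(l0 * c0),
                ReLU(),
                Dropout(cfg.dropout_rate, rng),
                Reshape((l0, c0)),
                UpSample1D(2),
                Conv1D(c0, f1, k, rng),
                BatchNorm(f1),
                ReLU(),
                Dropout(cfg.dropout_rate, rng),
                UpSample1D(2),
                Conv1D(f1, f2, k, rng),
                BatchNorm(f2),
                ReLU(),
                Dropout(cfg.dropout_rate, rng),
                _AdjustLength(cfg.out_length),
                Conv1D(f2, cfg.out_channels, k, rng),
            ]
        )

    @property
    def params(self):
        return self.embed.params + self.net.all_params

    @property
    def grads(self):
        return self.embed.grads + self.net.all_grads

    def forward(self, z: np.ndarray, label_idx: np.ndarray, training: bool) -> np.ndarray:
        e = self.embed.forward(label_idx)
        return self.net.forward(np.concatenate([z, e], axis=1), training=training)

    def backward(self, grad: np.ndarray) -> None:
        dx = self.net.backward(grad)
        self.embed.backward(dx[:, self.noise_dim :])


class _Discriminator:
    def __init__(self, cfg: "SpectralCGAN", n_classes: int, rng: np.random.Generator) -> None:
        self.out_channels = cfg.out_channels
        self.embed = Embedding(n_classes, cfg.disc_label_channels, rng)
        f1, f2 = cfg.disc_filters
        k = cfg.kernel_size
        flat_len = -(-cfg.out_length // 2)
        flat_len = -(-flat_len // 2)
        flat = flat_len * f2
        self.net = Sequential(
            [
                Conv1D(cfg.out_channels + cfg.disc_label_channels, f1, k, rng, stride=2),
                LeakyReLU(cfg.leaky_alpha),
                Dropout(cfg.dropout_rate, rng),
                Conv1D(f1, f2, k, rng, stride=2),
                LeakyReLU(cfg.leaky_alpha),
                Dropout(cfg.dropout_rate, rng),
                Flatten(),
                MinibatchDiscrimination(flat, cfg.minibatch_kernels, cfg.minibatch_dim, rng),
                Dense(flat + cfg.minibatch_kernels, 1, rng),
            ]
        )

    @property
    def params(self):
        return self.embed.params + self.net.all_params

    @property
    def grads(self):
        return self.embed.grads + self.net.all_grads

    def forward(self, x: np.ndarray, label_idx: np.ndarray, training: bool) -> np.ndarray:
        e = self.embed.forward(label_idx)  # (B, lc)
        tiled = np.broadcast_to(e[:, None, :], (x.shape[0], x.shape[1], e.shape[1]))
        return self.net.forward(np.concatenate([x, tiled], axis=2), training=training)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        dxin = self.net.backward(grad)
        self.embed.backward(dxin[:, :, self.out_channels :].sum(axis=1))
        return dxin[:, :, : self.out_channels]


# ---------------------------------------------------------------------------
# the estimator


class SpectralCGAN(BaseEstimator):
    """Class-conditioned GAN for fixed-length multichannel kinematic trials.

    Follows the sklearn estimator protocol: hyperparameters in ``__init__``,
    :meth:`fit` on ``(X, y)`` with X of shape (n_trials, length, channels)
    and integer class codes y, fitted state in trailing-underscore
    attributes, generation via :meth:`sample` / :meth:`sample_trials`.

    Parameters mirror the published recipe (defaults: two upsampling blocks
    with 256/128 filters, kernel 15, dropout 0.4, Adam lr 0.0003 with beta1
    0.5); unpublished sizes (noise dimension, batch size, epochs, spectral
    weight, minibatch-discrimination and discriminator sizes) are exposed
    here with documented defaults.
    """

    def __init__(
        self,
        noise_dim: int = 100,
        embed_dim: int = 16,
        reshape_length: int = 75,
        reshape_channels: int = 128,
        block_filters: tuple[int, int] = (256, 128),
        kernel_size: int = 15,
        dropout_rate: float = 0.4,
        out_channels: int = N_CHANNELS,
        out_length: int = TRIAL_LENGTH,
        disc_filters: tuple[int, int] = (128, 256),
        disc_label_channels: int = 4,
        leaky_alpha: float = 0.2,
        minibatch_kernels: int = 8,
        minibatch_dim: int = 4,
        spectral_weight: float = 1.0,
        spectral_mode: str = "paired",
        learning_rate: float = 3e-4,
        beta1: float = 0.5,
        batch_size: int = 32,
        epochs: int = 500,
        random_state: int | None = None,
    ) -> None:
        self.noise_dim = noise_dim
        self.embed_dim = embed_dim
        self.reshape_length = reshape_length
        self.reshape_channels = reshape_channels
        self.block_filters = block_filters
        self.kernel_size = kernel_size
        self.dropout_rate = dropout_rate
        self.out_channels = out_channels
        self.out_length = out_length
        self.disc_filters = disc_filters
        self.disc_label_channels = disc_label_channels
        self.leaky_alpha = leaky_alpha
        self.minibatch_kernels = minibatch_kernels
        self.minibatch_dim = minibatch_dim
        self.spectral_weight = spectral_weight
        self.spectral_mode = spectral_mode
        self.learning_rate = learning_rate
        self.beta1 = beta1
        self.batch_size = batch_size
        self.epochs = epochs
        self.random_state = random_state

    # -- fitting ------------------------------------------------------------

    def _validate(self) -> None:
        if self.kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd")
        if not 0 < self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in (0, 1)")
        if self.spectral_weight < 0:
            raise ValueError("spectral_weight must be nonnegative")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.reshape_length * 4 < self.out_length - self.out_length // 4:
            # upsampled length must land within pad/crop reach of the target
            raise ValueError(
                f"reshape_length {self.reshape_length} too short for out_length {self.out_length}"
            )

    def fit(self, X: np.ndarray, y: np.ndarray) -> "SpectralCGAN":
        """Adversarial training on standardized trials.

        X: (n, out_length, out_channels) signals in physical units;
        y: integer class codes. Records per-epoch discriminator loss,
        generator adversarial loss and spectral loss in ``loss_history_``.
        """
        self._validate()
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if X.ndim != 3 or X.shape[1:] != (self.out_length, self.out_channels):
            raise ValueError(
                f"X must be (n, {self.out_length}, {self.out_channels}), got {X.shape}"
            )
        if X.shape[0] == 0:
            raise ValueError("empty dataset")

        self.classes_ = np.unique(y)
        label_idx = np.searchsorted(self.classes_, y)

        self.channel_means_ = X.mean(axis=(0, 1))
        self.channel_sds_ = X.std(axis=(0, 1))
        self.channel_sds_ = np.where(self.channel_sds_ > 0, self.channel_sds_, 1.0)
        xs = (X - self.channel_means_) / self.channel_sds_

        rng = np.random.default_rng(self.random_state)
        self._rng = rng
        n_classes = len(self.classes_)
        self.generator_ = _Generator(self, n_classes, rng)
        self.discriminator_ = _Discriminator(self, n_classes, rng)
        opt_g = Adam(self.generator_.params, lr=self.learning_rate, beta1=self.beta1)
        opt_d = Adam(self.discriminator_.params, lr=self.learning_rate, beta1=self.beta1)
        spec = _SpectralGrad(self.out_length) if self.spectral_weight > 0 else None

        n = X.shape[0]
        bs = min(self.batch_size, n)
        history = []
        for epoch in range(self.epochs):
            order = rng.permutation(n)
            d_losses, g_adv_losses, g_spec_losses = [], [], []
            for start in range(0, n, bs):
                take = order[start : start + bs]
                if take.size < 2:
                    continue  # minibatch features need company
                real = xs[take]
                lab = label_idx[take]
                b = real.shape[0]

                # discriminator step: real -> 1, fake -> 0
                z = rng.standard_normal((b, self.noise_dim))
                fake = self.generator_.forward(z, lab, training=True)
                logits_r = self.discriminator_.forward(real, lab, training=True)
                loss_r, dlog_r = sigmoid_bce_with_logits(logits_r, 1.0)
                self.discriminator_.backward(dlog_r)
                grads_real = [g.copy() for g in self.discriminator_.grads]
                logits_f = self.discriminator_.forward(fake, lab, training=True)
                loss_f, dlog_f = sigmoid_bce_with_logits(logits_f, 0.0)
                self.discriminator_.backward(dlog_f)
                opt_d.step([gr + gf for gr, gf in zip(grads_real, self.discriminator_.grads)])
                d_losses.append(loss_r + loss_f)

                # generator step: fool the discriminator + match spectra
                z2 = rng.standard_normal((b, self.noise_dim))
                fake2 = self.generator_.forward(z2, lab, training=True)
                logits_g = self.discriminator_.forward(fake2, lab, training=True)
                loss_g, dlog_g = sigmoid_bce_with_logits(logits_g, 1.0)
                dfake = self.discriminator_.backward(dlog_g)
                self.generator_.backward(dfake)
                if spec is not None:
                    # the spectral loss shapes what sampling actually emits:
                    # evaluate it on the inference-mode pass (dropout off,
                    # running batch-norm statistics), not on the dropout-noised
                    # training pass, and add its gradient to the adversarial one
                    g_adv = [g.copy() for g in self.generator_.grads]
                    fake_eval = self.generator_.forward(z2, lab, training=False)
                    loss_s, dspec = spec.loss_and_grad(real, fake_eval, self.spectral_mode)
                    self.generator_.backward(self.spectral_weight * dspec)
                    opt_g.step([a + s for a, s in zip(g_adv, self.generator_.grads)])
                else:
                    loss_s = 0.0
                    opt_g.step(self.generator_.grads)
                g_adv_losses.append(loss_g)
                g_spec_losses.append(loss_s)

            row = {
                "epoch": epoch,
                "d_loss": float(np.mean(d_losses)),
                "g_adversarial": float(np.mean(g_adv_losses)),
                "g_spectral": float(np.mean(g_spec_losses)),
            }
            if not all(np.isfinite(v) for v in row.values()):
                raise RuntimeError(f"GAN training diverged at epoch {epoch}: {row}")
            history.append(row)
        self.loss_history_ = pd.DataFrame(history)
        return self

    # -- generation ---------------------------------------------------------

    def _check_fitted(self) -> None:
        if not hasattr(self, "generator_"):
            raise RuntimeError("SpectralCGAN is not fitted")

    def _label_index(self, label: int) -> int:
        pos = np.searchsorted(self.classes_, label)
        if pos >= len(self.classes_) or self.classes_[pos] != label:
            raise ValueError(
                f"class {label} was not present in the training data (known: {list(self.classes_)})"
            )
        return int(pos)

    def generator_forward(self, z: np.ndarray, labels: np.ndarray) -> np.ndarray:
        """Raw generator output in standardized units (inference mode)."""
        self._check_fitted()
        z = np.atleast_2d(np.asarray(z, dtype=float))
        if z.shape[1] != self.noise_dim:
            raise ValueError(f"noise vectors must have {self.noise_dim} entries")
        labels = np.asarray(labels, dtype=int).reshape(-1)
        idx = np.array([self._label_index(c) for c in labels])
        return self.generator_.forward(z, idx, training=False)

    def sample(
        self,
        label: int,
        n: int,
        rng: np.random.Generator | int | None = None,
        lowpass: bool = False,
    ) -> np.ndarray:
        """Generate ``n`` trials of class ``label`` in physical units."""
        self._check_fitted()
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        z = rng.standard_normal((n, self.noise_dim))
        out = self.generator_forward(z, np.full(n, label))
        out = out * self.channel_sds_ + self.channel_means_
        if lowpass:
            out = lowpass_2hz(out)
        return out

    def sample_trials(
        self,
        label: int,
        n: int,
        rng: np.random.Generator | int | None = None,
        lowpass: bool = False,
    ) -> Dataset:
        """Generate ``n`` synthetic :class:`KinematicTrial`s of class ``label``."""
        if (self.out_length, self.out_channels) != (TRIAL_LENGTH, N_CHANNELS):
            raise ValueError("sample_trials requires the full 300x9 trial geometry")
        signals = self.sample(label, n, rng=rng, lowpass=lowpass)
        task_index, group_index = decode_class(label)
        return Dataset(
            [
                KinematicTrial(
                    signal=signals[i],
                    task=TASKS[task_index],
                    group=GROUPS[group_index],
                    subject_id="cgan",
                    provenance="synthetic",
                )
                for i in range(n)
            ]
        )

    def standardize(self, X: np.ndarray) -> np.ndarray:
        self._check_fitted()
        return (np.asarray(X, dtype=float) - self.channel_means_) / self.channel_sds_

    # -- persistence --------------------------------------------------------

    def _stateful_arrays(self) -> list[np.ndarray]:
        arrays = list(self.generator_.params) + list(self.discriminator_.params)
        for model in (self.generator_, self.discriminator_):
            for layer in model.net.layers:
                if isinstance(layer, BatchNorm):
                    arrays.extend([layer.running_mean, layer.running_var])
        return arrays

    def save(self, path) -> None:
        """Persist the trained bundle: weights, channel stats, config, history."""
        self._check_fitted()
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        arrays = {f"a{i:04d}": a for i, a in enumerate(self._stateful_arrays())}
        np.savez(path / "weights.npz", classes=self.classes_,
                 channel_means=self.channel_means_, channel_sds=self.channel_sds_, **arrays)
        (path / "config.json").write_text(json.dumps(self.get_params(), default=list, indent=2))
        self.loss_history_.to_csv(path / "loss_history.csv", index=False)

    @classmethod
    def load(cls, path) -> "SpectralCGAN":
        path = Path(path)
        params = json.loads((path / "config.json").read_text())
        for key in ("block_filters", "disc_filters"):
            params[key] = tuple(params[key])
        est = cls(**params)
        with np.load(path / "weights.npz") as f:
            est.classes_ = f["classes"]
            est.channel_means_ = f["channel_means"]
            est.channel_sds_ = f["channel_sds"]
            rng = np.random.default_rng(0)
            est.generator_ = _Generator(est, len(est.classes_), rng)
            est.discriminator_ = _Discriminator(est, len(est.classes_), rng)
            for i, target in enumerate(est._stateful_arrays()):
                target[...] = f[f"a{i:04d}"]
        est.loss_history_ = pd.read_csv(path / "loss_history.csv")
        return est


def train_cgan(dataset: Dataset, **params) -> SpectralCGAN:
    """Fit a :class:`SpectralCGAN` on a :class:`Dataset` (thin wrapper)."""
    est = SpectralCGAN(**params)
    return est.fit(dataset.signals(), dataset.labels)
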