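"""Fully convolutional network for classifying 5-s, 9-channel trials.

Architecture: Conv1D(64, kernel 3, ReLU) -> MaxPool(2) -> Conv1D(128,
kernel 3, ReLU) -> MaxPool(2) -> Flatten -> Dense(100, ReLU) ->
Dropout(0.5) -> Dense(n_classes, softmax), trained with Adam and sparse
categorical cross-entropy. Convolutions use 'same' padding so the 300-long
input shrinks 300 -> 150 -> 75 under the two pools, giving a flatten width
of 75 * 128 = 9600.

The default target is the 10 tasks; training on all 30 task-by-impairment
codes works the same way (``n_classes`` follows the labels passed to fit).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .channels import N_CHANNELS, TRIAL_LENGTH
from .nn import (
    Adam,
    Conv1D,
    Dense,
    Dropout,
    Flatten,
    MaxPool1D,
    ReLU,
    Sequential,
    softmax_cross_entropy,
)


class FcnTaskClassifier(BaseEstimator, ClassifierMixin):
    """1-D fully convolutional trial classifier (sklearn estimator protocol).

    X has shape (n_trials, length, channels); y holds integer labels (task
    indices or composite class codes). Epochs and batch size are not part
    of the published recipe and default to 100 / 32.
    """

    def __init__(
        self,
        conv1_filters: int = 64,
        conv2_filters: int = 128,
        kernel_size: int = 3,
        pool: int = 2,
        dense_units: int = 100,
        dropout_rate: float = 0.5,
        learning_rate: float = 0.001,
        epochs: int = 100,
        batch_size: int = 32,
        input_length: int = TRIAL_LENGTH,
        input_channels: int = N_CHANNELS,
        random_state: int | None = None,
    ) -> None:
        self.conv1_filters = conv1_filters
        self.conv2_filters = conv2_filters
        self.kernel_size = kernel_size
        self.pool = pool
        self.dense_units = dense_units
        self.dropout_rate = dropout_rate
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.input_length = input_length
        self.input_channels = input_channels
        self.random_state = random_state

    def _build(self, n_classes: int, rng: np.random.Generator) -> Sequential:
        if self.input_length % (self.pool**2):
            raise ValueError(
                f"input_length {self.input_length} incompatible with two pool-{self.pool} stages"
            )
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if n_classes < 2:
            raise ValueError("need at least 2 classes")
        flat = (self.input_length // self.pool**2) * self.conv2_filters
        return Sequential(
            [
                Conv1D(self.input_channels, self.conv1_filters, self.kernel_size, rng),
                ReLU(),
                MaxPool1D(self.pool),
                Conv1D(self.conv1_filters, self.conv2_filters, self.kernel_size, rng),
                ReLU(),
                MaxPool1D(self.pool),
                Flatten(),
                Dense(flat, self.dense_units, rng),
                ReLU(),
                Dropout(self.dropout_rate, rng),
                Dense(self.dense_units, n_classes, rng),
            ]
        )

    def n_parameters(self) -> int:
        """Total trainable parameter count of the built network."""
        net = getattr(self, "net_", None)
        if net is None:
            net = self._build(10, np.random.default_rng(0))
        return sum(p.size for p in net.all_params)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "FcnTaskClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if X.ndim != 3 or X.shape[1:] != (self.input_length, self.input_channels):
            raise ValueError(
                f"X must be (n, {self.input_length}, {self.input_channels}), got {X.shape}"
            )
        self.classes_ = np.unique(y)
        yi = np.searchsorted(self.classes_, y)
        rng = np.random.default_rng(self.random_state)
        self.net_ = self._build(len(self.classes_), rng)
        # standardize per channel over the training set; mixed cm/rad
        # magnitudes otherwise skew the early convolution layers
        self.channel_means_ = X.mean(axis=(0, 1))
        self.channel_sds_ = np.where(X.std(axis=(0, 1)) > 0, X.std(axis=(0, 1)), 1.0)
        xs = (X - self.channel_means_) / self.channel_sds_

        opt = Adam(self.net_.all_params, lr=self.learning_rate)
        n = X.shape[0]
        bs = min(self.batch_size, n)
        self.loss_curve_ = []
        for _ in range(self.epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, bs):
                take = order[start : start + bs]
                logits = self.net_.forward(xs[take], training=True)
                loss, _, dlogits = softmax_cross_entropy(logits, yi[take])
                if not np.isfinite(loss):
                    raise RuntimeError(f"training diverged (loss={loss})")
                self.net_.backward(dlogits)
                opt.step(self.net_.all_grads)
                losses.append(loss)
            self.loss_curve_.append(float(np.mean(losses)))
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        if not hasattr(self, "net_"):
            raise RuntimeError("classifier is not fitted")
        X = np.asarray(X, dtype=float)
        xs = (X - self.channel_means_) / self.channel_sds_
        probs = []
        for start in range(0, X.shape[0], 256):
            logits = self.net_.forward(xs[start : start + 256], training=False)
            z = logits - logits.max(axis=1, keepdims=True)
            ez = np.exp(z)
            probs.append(ez / ez.sum(axis=1, keepdims=True))
        return np.vstack(probs)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[self.predict_proba(X).argmax(axis=1)]


def predict_confusion(model: FcnTaskClassifier, X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Confusion-count matrix over the model's class set.

    Rows are true classes, columns predicted classes (both in ``classes_``
    order); entries sum to the number of test trials.
    """
    y = np.asarray(y, dtype=int)
    pred = model.predict(X)
    k = len(model.classes_)
    ti = np.searchsorted(model.classes_, y)
    pi = np.searchsorted(model.classes_, pred)
    conf = np.zeros((k, k), dtype=int)
    np.add.at(conf, (ti, pi), 1)
    return conf
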