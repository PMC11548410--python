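"""Numerically stable classification losses with analytic gradients."""

from __future__ import annotations

import numpy as np


def sigmoid_bce_with_logits(logits: np.ndarray, targets: np.ndarray):
    """Mean binary cross-entropy on raw logits.

    Returns (loss, dloss/dlogits). Uses the log-sum-exp form, stable for
    large |logits|.
    """
    z = np.asarray(logits, dtype=float).reshape(-1)
    y = np.broadcast_to(np.asarray(targets, dtype=float), z.shape)
    loss = float(np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))))
    sig = 1.0 / (1.0 + np.exp(-z))
    grad = ((sig - y) / z.size).reshape(np.shape(logits))
    return loss, grad


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean sparse categorical cross-entropy on raw logits.

    Returns (loss, probabilities, dloss/dlogits).
    """
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=1, keepdims=True)
    n = z.shape[0]
    labels = np.asarray(labels, dtype=int)
    loss = float(-np.mean(np.log(p[np.arange(n), labels] + 1e-12)))
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, p, grad / n
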