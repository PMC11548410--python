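"""Layer primitives with explicit forward/backward passes.

Conventions: time-series tensors are (batch, length, channels); dense
tensors are (batch, features). Each layer caches what its backward pass
needs during forward; ``backward`` returns the gradient w.r.t. the layer
input and fills ``self.grads`` (parallel to ``self.params``). Stateless
layers keep empty param lists.
"""

from __future__ import annotations

import numpy as np


class Layer:
    def __init__(self) -> None:
        self.params: list[np.ndarray] = []
        self.grads: list[np.ndarray] = []

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.W = _glorot(rng, (in_features, out_features), in_features, out_features)
        self.b = np.zeros(out_features)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, training=True):
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad):
        self.grads[0][...] = self._x.T @ grad
        self.grads[1][...] = grad.sum(axis=0)
        return grad @ self.W.T


class Conv1D(Layer):
    """1-D convolution (cross-correlation) with 'same' coverage.

    Output length is ceil(L / stride); zero padding is split as evenly as
    possible around the input. Implemented as one small gemm per kernel tap
    on strided views of the padded input, which avoids materializing an
    im2col buffer.
    """

    def __init__(
        self,
        in_channels: int,
        filters: int,
        kernel_size: int,
        rng: np.random.Generator,
        stride: int = 1,
    ) -> None:
        super().__init__()
        self.k = kernel_size
        self.stride = stride
        self.cin = in_channels
        fan_in = kernel_size * in_channels
        # W[k] is the (C_in, F) weight slice of kernel tap k
        self.W = _glorot(rng, (kernel_size, in_channels, filters), fan_in, kernel_size * filters)
        self.b = np.zeros(filters)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def _geometry(self, length: int) -> tuple[int, int, int]:
        out_len = -(-length // self.stride)
        pad_total = max((out_len - 1) * self.stride + self.k - length, 0)
        pad_left = pad_total // 2
        return out_len, pad_left, pad_total - pad_left

    def _tap(self, arr: np.ndarray, k: int, out_len: int) -> np.ndarray:
        return arr[:, k : k + (out_len - 1) * self.stride + 1 : self.stride, :]

    def forward(self, x, training=True):
        b, length, cin = x.shape
        if cin != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {cin}")
        out_len, pl, pr, = self._geometry(length)
        self._xp = np.pad(x, ((0, 0), (pl, pr), (0, 0)))
        self._shape = (b, length, pl, pr, out_len)
        out = np.broadcast_to(self.b, (b, out_len, self.W.shape[2])).copy()
        for k in range(self.k):
            out += np.matmul(self._tap(self._xp, k, out_len), self.W[k])
        return out

    def backward(self, grad):
        b, length, pl, pr, out_len = self._shape
        grad2d = grad.reshape(b * out_len, -1)
        self.grads[1][...] = grad.sum(axis=(0, 1))
        dxp = np.zeros_like(self._xp)
        for k in range(self.k):
            xk = self._tap(self._xp, k, out_len).reshape(b * out_len, self.cin)
            self.grads[0][k] = xk.T @ grad2d
            self._tap(dxp, k, out_len)[...] += np.matmul(grad, self.W[k].T)
        return dxp[:, pl : pl + length, :]


class MaxPool1D(Layer):
    def __init__(self, pool: int = 2) -> None:
        super().__init__()
        self.pool = pool

    def forward(self, x, training=True):
        b, length, c = x.shape
        if length % self.pool:
            raise ValueError(f"length {length} not divisible by pool {self.pool}")
        xr = x.reshape(b, length // self.pool, self.pool, c)
        self._arg = xr.argmax(axis=2)
        self._shape = x.shape
        return xr.max(axis=2)

    def backward(self, grad):
        b, lout, c = grad.shape
        dxr = np.zeros((b, lout, self.pool, c))
        bi, li, ci = np.ogrid[:b, :lout, :c]
        dxr[bi, li, self._arg, ci] = grad
        return dxr.reshape(self._shape)


class UpSample1D(Layer):
    """Nearest-neighbour upsampling along the time axis."""

    def __init__(self, factor: int = 2) -> None:
        super().__init__()
        self.factor = factor

    def forward(self, x, training=True):
        return np.repeat(x, self.factor, axis=1)

    def backward(self, grad):
        b, lout, c = grad.shape
        return grad.reshape(b, lout // self.factor, self.factor, c).sum(axis=2)


class BatchNorm(Layer):
    """Batch normalization per feature channel.

    For (B, L, C) tensors statistics pool over batch and time; for (B, F)
    over the batch. Running statistics are used in inference mode, so
    generation is deterministic given the weights.
    """

    def __init__(self, num_features: int, momentum: float = 0.9, eps: float = 1e-5) -> None:
        super().__init__()
        self.gamma = np.ones(num_features)
        self.beta = np.zeros(num_features)
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(num_features)
        self.running_var = np.ones(num_features)

    def forward(self, x, training=True):
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean) / self._std
        self._axes = axes
        self._m = int(np.prod([x.shape[a] for a in axes])) if training else 0
        return self.gamma * self._xhat + self.beta

    def backward(self, grad):
        axes = self._axes
        self.grads[0][...] = (grad * self._xhat).sum(axis=axes)
        self.grads[1][...] = grad.sum(axis=axes)
        dxhat = grad * self.gamma
        if not self._m:  # inference mode: mean/var are constants
            return dxhat / self._std
        m = self._m
        return (
            dxhat - dxhat.mean(axis=axes) - self._xhat * (dxhat * self._xhat).mean(axis=axes)
        ) / self._std


class Dropout(Layer):
    """Inverted dropout; identity in inference mode."""

    def __init__(self, rate: float, rng: np.random.Generator) -> None:
        super().__init__()
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x, training=True):
        if not training or self.rate == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class ReLU(Layer):
    def forward(self, x, training=True):
        self._pos = x > 0
        return np.where(self._pos, x, 0.0)

    def backward(self, grad):
        return grad * self._pos


class LeakyReLU(Layer):
    def __init__(self, alpha: float = 0.2) -> None:
        super().__init__()
        self.alpha = alpha

    def forward(self, x, training=True):
        self._pos = x > 0
        return np.where(self._pos, x, self.alpha * x)

    def backward(self, grad):
        return np.where(self._pos, grad, self.alpha * grad)


class Flatten(Layer):
    def forward(self, x, training=True):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Reshape(Layer):
    def __init__(self, target: tuple[int, ...]) -> None:
        super().__init__()
        self.target = target

    def forward(self, x, training=True):
        self._shape = x.shape
        return x.reshape((x.shape[0],) + self.target)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Embedding(Layer):
    """Lookup table for integer class labels."""

    def __init__(self, n_embeddings: int, dim: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.W = rng.normal(0.0, 0.05, size=(n_embeddings, dim))
        self.params = [self.W]
        self.grads = [np.zeros_like(self.W)]

    def forward(self, idx, training=True):
        self._idx = np.asarray(idx, dtype=int)
        return self.W[self._idx]

    def backward(self, grad):
        self.grads[0][...] = 0.0
        np.add.at(self.grads[0], self._idx, grad)
        return None  # integer inputs carry no gradient


class MinibatchDiscrimination(Layer):
    """Within-batch similarity features (mode-collapse counter-measure).

    Each sample's feature vector f_i is projected through a learned tensor T
    into ``num_kernels`` rows M_i of dimension ``kernel_dim``; the b-th
    output feature is sum over the *other* batch members of
    exp(-||M_{i,b} - M_{j,b}||_1). Identical samples in a batch give large
    values, diverse ones small values; a batch of size 1 gives zeros (the
    sum over j != i is empty). The features are concatenated to the input.
    """

    def __init__(
        self, in_features: int, num_kernels: int, kernel_dim: int, rng: np.random.Generator
    ) -> None:
        super().__init__()
        self.num_kernels = num_kernels
        self.kernel_dim = kernel_dim
        self.T = rng.normal(0.0, 0.1, size=(in_features, num_kernels * kernel_dim))
        self.params = [self.T]
        self.grads = [np.zeros_like(self.T)]

    def features(self, f: np.ndarray) -> np.ndarray:
        """The (B, num_kernels) similarity features alone (no concat)."""
        return self.forward(f)[:, f.shape[1] :]

    def forward(self, f, training=True):
        b = f.shape[0]
        m = (f @ self.T).reshape(b, self.num_kernels, self.kernel_dim)
        diff = m[:, None, :, :] - m[None, :, :, :]  # (B, B, K, C)
        l1 = np.abs(diff).sum(axis=-1)
        expneg = np.exp(-l1)
        eye = np.eye(b, dtype=bool)
        expneg[eye] = 0.0
        self._f, self._m, self._diff, self._expneg = f, m, diff, expneg
        return np.concatenate([f, expneg.sum(axis=1)], axis=1)

    def backward(self, grad):
        f, diff, expneg = self._f, self._diff, self._expneg
        b, a = f.shape
        df = grad[:, :a].copy()
        do = grad[:, a:]  # (B, K)
        dexp = np.broadcast_to(do[:, None, :], expneg.shape).copy()
        dexp[np.eye(b, dtype=bool)] = 0.0
        dl1 = -expneg * dexp
        ddiff = dl1[..., None] * np.sign(diff)
        dm = ddiff.sum(axis=1) - ddiff.sum(axis=0)
        dmflat = dm.reshape(b, -1)
        self.grads[0][...] = f.T @ dmflat
        return df + dmflat @ self.T.T


class Sequential(Layer):
    def __init__(self, layers: list[Layer]) -> None:
        super().__init__()
        self.layers = layers

    @property
    def all_params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def all_grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def forward(self, x, training=True):
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad
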