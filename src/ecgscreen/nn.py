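"""A small, seeded NumPy engine for 1D convolutional classifiers.

Implements exactly the layer vocabulary the segment classifier needs —
valid (unpadded) 1D convolution, batch normalization, max/average pooling,
ReLU, dropout, a dense layer with L2 weight penalty, and a softmax
cross-entropy head — together with the Adam optimizer.  Everything runs in
float32 with the heavy lifting done by BLAS matmuls over im2col views, so a
few hundred 5400-sample segments train in minutes on one CPU core.

Tensor layout is channels-last: ``(batch, length, channels)``.

Each layer exposes ``forward(x, training)`` and ``backward(dout)``;
parameters and their gradients are flat lists consumed by :class:`Adam`.
Gradients are exact (verified against central finite differences in the
test suite).
"""

from __future__ import annotations

import numpy as np


class Layer:
    """Base class: stateless unless it has parameters."""

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def glorot_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


class Conv1D(Layer):
    """Valid (no padding) 1D convolution; output length floor((L-k)/s)+1."""

    def __init__(self, in_channels: int, filters: int, kernel_size: int, stride: int,
                 rng: np.random.Generator, first_layer: bool = False):
        self.kernel_size = kernel_size
        self.stride = stride
        fan_in = kernel_size * in_channels
        self.W = glorot_uniform(rng, (kernel_size * in_channels, filters), fan_in, filters)
        self.b = np.zeros(filters, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        # The input-gradient scatter is skipped for the first layer.
        self.first_layer = first_layer
        self._cache = None

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def _window_index(self, length: int) -> np.ndarray:
        l_out = (length - self.kernel_size) // self.stride + 1
        if self.kernel_size > length or l_out < 1:
            raise ValueError(
                f"kernel {self.kernel_size} does not fit input length {length}"
            )
        return (
            np.arange(l_out)[:, None] * self.stride + np.arange(self.kernel_size)[None, :]
        )

    def forward(self, x, training=False):
        b, length, c = x.shape
        idx = self._window_index(length)
        cols = x[:, idx, :].reshape(b, idx.shape[0], self.kernel_size * c)
        out = cols @ self.W + self.b
        self._cache = (cols, idx, x.shape)
        return out

    def backward(self, dout):
        cols, idx, x_shape = self._cache
        b, length, c = x_shape
        # dout: (b, l_out, filters)
        self.dW[...] = np.tensordot(cols, dout, axes=([0, 1], [0, 1]))
        self.db[...] = dout.sum(axis=(0, 1))
        if self.first_layer:
            return None
        dcols = (dout @ self.W.T).reshape(b, idx.shape[0], self.kernel_size, c)
        dx = np.zeros(x_shape, dtype=np.float32)
        np.add.at(dx, (slice(None), idx), dcols)
        return dx


class BatchNorm(Layer):
    """Per-channel batch normalization over (batch, length) with learned affine."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-3):
        self.gamma = np.ones(channels, dtype=np.float32)
        self.beta = np.zeros(channels, dtype=np.float32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def grads(self):
        return [self.dgamma, self.dbeta]

    def forward(self, x, training=False):
        if training:
            mean = x.mean(axis=(0, 1))
            var = x.var(axis=(0, 1))
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mean
            ).astype(np.float32)
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * var
            ).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv_std
        self._cache = (xhat, inv_std, x.shape, training)
        return (self.gamma * xhat + self.beta).astype(np.float32)

    def backward(self, dout):
        xhat, inv_std, shape, training = self._cache
        self.dgamma[...] = (dout * xhat).sum(axis=(0, 1))
        self.dbeta[...] = dout.sum(axis=(0, 1))
        if not training:
            return (dout * self.gamma * inv_std).astype(np.float32)
        n = shape[0] * shape[1]
        dxhat = dout * self.gamma
        dx = (
            inv_std
            / n
            * (
                n * dxhat
                - dxhat.sum(axis=(0, 1))
                - xhat * (dxhat * xhat).sum(axis=(0, 1))
            )
        )
        return dx.astype(np.float32)


class MaxPool1D(Layer):
    """Non-overlapping max pooling; trailing remainder truncated (floor(L/p))."""

    def __init__(self, pool_size: int):
        self.pool_size = pool_size
        self._cache = None

    def forward(self, x, training=False):
        b, length, c = x.shape
        l_out = length // self.pool_size
        win = x[:, : l_out * self.pool_size, :].reshape(b, l_out, self.pool_size, c)
        argmax = win.argmax(axis=2)
        out = np.take_along_axis(win, argmax[:, :, None, :], axis=2)[:, :, 0, :]
        self._cache = (argmax, x.shape, l_out)
        return out

    def backward(self, dout):
        argmax, x_shape, l_out = self._cache
        b, length, c = x_shape
        dwin = np.zeros((b, l_out, self.pool_size, c), dtype=np.float32)
        np.put_along_axis(dwin, argmax[:, :, None, :], dout[:, :, None, :], axis=2)
        dx = np.zeros(x_shape, dtype=np.float32)
        dx[:, : l_out * self.pool_size, :] = dwin.reshape(b, l_out * self.pool_size, c)
        return dx


class AvgPool1D(Layer):
    """Non-overlapping average pooling; trailing remainder truncated."""

    def __init__(self, pool_size: int):
        self.pool_size = pool_size
        self._cache = None

    def forward(self, x, training=False):
        b, length, c = x.shape
        l_out = length // self.pool_size
        win = x[:, : l_out * self.pool_size, :].reshape(b, l_out, self.pool_size, c)
        self._cache = (x.shape, l_out)
        return win.mean(axis=2)

    def backward(self, dout):
        x_shape, l_out = self._cache
        b, length, c = x_shape
        dx = np.zeros(x_shape, dtype=np.float32)
        spread = np.repeat(dout / self.pool_size, self.pool_size, axis=1)
        dx[:, : l_out * self.pool_size, :] = spread
        return dx


class ReLU(Layer):
    def forward(self, x, training=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class Flatten(Layer):
    def forward(self, x, training=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0 <= rate < 1:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng = rng
        self._mask = None

    def forward(self, x, training=False):
        if not training or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dout):
        if self._mask is None:
            return dout
        return dout * self._mask


class Dense(Layer):
    """Fully connected layer with an L2 penalty on the weight matrix."""

    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 l2: float = 0.0):
        self.W = glorot_uniform(rng, (in_features, out_features), in_features, out_features)
        self.b = np.zeros(out_features, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.l2 = l2
        self._x = None

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def l2_loss(self) -> float:
        return float(self.l2 * np.sum(self.W.astype(np.float64) ** 2))

    def forward(self, x, training=False):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout):
        self.dW[...] = self._x.T @ dout + 2.0 * self.l2 * self.W
        self.db[...] = dout.sum(axis=0)
        return dout @ self.W.T


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(probs: np.ndarray, y: np.ndarray) -> float:
    """Mean categorical cross-entropy; y holds integer class indices."""
    eps = 1e-12
    return float(-np.log(probs[np.arange(len(y)), y] + eps).mean())


class Sequential:
    """An ordered stack of layers with a softmax cross-entropy head."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def grads(self):
        return [g for layer in self.layers for g in layer.grads()]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Class probabilities, shape (batch, n_classes)."""
        out = np.asarray(x, dtype=np.float32)
        for layer in self.layers:
            out = layer.forward(out, training=training)
        return softmax(out)

    def loss(self, probs: np.ndarray, y: np.ndarray) -> float:
        reg = sum(l.l2_loss() for l in self.layers if isinstance(l, Dense))
        return cross_entropy(probs, y) + reg

    def backward(self, probs: np.ndarray, y: np.ndarray) -> None:
        """Backpropagate the softmax cross-entropy gradient through the stack."""
        n = len(y)
        dlogits = probs.copy()
        dlogits[np.arange(n), y] -= 1.0
        dout = (dlogits / n).astype(np.float32)
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
            if dout is None:  # first conv skips the input gradient
                break


class Adam:
    """Adam optimizer over a flat parameter list (updates in place)."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = self.beta1 * m + (1 - self.beta1) * g
            v[...] = self.beta2 * v + (1 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
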