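"""Minimal feed-forward network engine used by the fitness predictors.

Layers operate on float64 arrays.  Sequence inputs are one-hot tensors of
shape ``(batch, L, A)``; dense layers act on flattened ``(batch, features)``
arrays.  Backpropagation is written out explicitly per layer and parameters
are updated with Adam.  Everything is seeded through numpy Generators, so a
given initialization seed fully determines the initial parameters.
"""

from __future__ import annotations

import numpy as np


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Dense(Layer):
    """Affine map on ``(batch, n_in)`` arrays; Glorot-uniform init."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.w = rng.uniform(-limit, limit, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.grads[0][...] = self._x.T @ grad
        self.grads[1][...] = grad.sum(axis=0)
        return grad @ self.w.T


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class Conv1D(Layer):
    """1-D convolution along the sequence axis with 'same' zero padding.

    Input ``(batch, L, c_in)`` -> output ``(batch, L, c_out)``.  Weights are
    shared across positions (translation equivariance up to edge effects).
    Implemented by an im2col gather followed by a single matmul.
    """

    def __init__(
        self, c_in: int, c_out: int, kernel_size: int, rng: np.random.Generator
    ) -> None:
        super().__init__()
        if kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd for 'same' padding")
        self.k = kernel_size
        self.c_in = c_in
        fan_in = kernel_size * c_in
        limit = np.sqrt(6.0 / (fan_in + c_out))
        self.w = rng.uniform(-limit, limit, size=(fan_in, c_out))
        self.b = np.zeros(c_out)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        b, L, c = x.shape
        pad = self.k // 2
        xp = np.pad(x, ((0, 0), (pad, pad), (0, 0)))
        windows = np.lib.stride_tricks.sliding_window_view(xp, self.k, axis=1)
        # windows: (b, L, c, k) -> (b, L, k*c)
        return windows.transpose(0, 1, 3, 2).reshape(b, L, self.k * c)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._cols = self._im2col(x)
        self._in_shape = x.shape
        b, L, _ = x.shape
        out = self._cols.reshape(b * L, -1) @ self.w + self.b
        return out.reshape(b, L, -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        b, L, c_out = grad.shape
        g2 = grad.reshape(b * L, c_out)
        self.grads[0][...] = self._cols.reshape(b * L, -1).T @ g2
        self.grads[1][...] = g2.sum(axis=0)
        dcols = (g2 @ self.w.T).reshape(b, L, self.k, self.c_in)
        pad = self.k // 2
        dx = np.zeros((b, L + 2 * pad, self.c_in))
        for j in range(self.k):
            dx[:, j : j + L, :] += dcols[:, :, j, :]
        return dx[:, pad : pad + L, :]


class GraphConv(Layer):
    """Graph convolution ``H' = A_hat @ X @ W + b`` with a fixed propagator.

    ``a_hat`` is the symmetrically normalized adjacency with self-loops
    (Kipf-Welling convention), shape ``(L, L)``.  Input ``(batch, L, c_in)``.
    """

    def __init__(
        self, a_hat: np.ndarray, c_in: int, c_out: int, rng: np.random.Generator
    ) -> None:
        super().__init__()
        self.a_hat = np.asarray(a_hat, dtype=np.float64)
        limit = np.sqrt(6.0 / (c_in + c_out))
        self.w = rng.uniform(-limit, limit, size=(c_in, c_out))
        self.b = np.zeros(c_out)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._ax = np.einsum("lm,bmc->blc", self.a_hat, x)
        b, L, _ = x.shape
        out = self._ax.reshape(b * L, -1) @ self.w + self.b
        return out.reshape(b, L, -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        b, L, c_out = grad.shape
        g2 = grad.reshape(b * L, c_out)
        self.grads[0][...] = self._ax.reshape(b * L, -1).T @ g2
        self.grads[1][...] = g2.sum(axis=0)
        dax = (g2 @ self.w.T).reshape(b, L, -1)
        # a_hat is symmetric, so the transpose propagator equals a_hat
        return np.einsum("lm,bmc->blc", self.a_hat.T, dax)


def normalize_adjacency(adjacency: np.ndarray) -> np.ndarray:
    """Symmetric normalization with self-loops: ``D^-1/2 (A + I) D^-1/2``."""
    a = np.asarray(adjacency, dtype=np.float64) + np.eye(adjacency.shape[0])
    deg = a.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(deg)
    return a * inv_sqrt[:, None] * inv_sqrt[None, :]


class Network:
    """A layer stack with MSE loss and an Adam optimizer."""

    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers
        self._adam_m: list[np.ndarray] | None = None
        self._adam_v: list[np.ndarray] | None = None
        self._adam_t = 0

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def n_params(self) -> int:
        return sum(p.size for p in self.params)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)[:, 0]

    def backward(self, grad: np.ndarray) -> None:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def train_step(
        self, x: np.ndarray, y: np.ndarray, lr: float, betas=(0.9, 0.999), eps=1e-8
    ) -> float:
        out = self.forward(x)[:, 0]
        resid = out - y
        loss = float(np.mean(resid ** 2))
        grad = (2.0 / len(y)) * resid[:, None]
        self.backward(grad)
        if self._adam_m is None:
            self._adam_m = [np.zeros_like(p) for p in self.params]
            self._adam_v = [np.zeros_like(p) for p in self.params]
        self._adam_t += 1
        b1, b2 = betas
        t = self._adam_t
        for p, g, m, v in zip(self.params, self.grads, self._adam_m, self._adam_v):
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g ** 2
            m_hat = m / (1 - b1 ** t)
            v_hat = v / (1 - b2 ** t)
            p -= lr * m_hat / (np.sqrt(v_hat) + eps)
        return loss

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.params, weights):
            p[...] = w
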