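"""A compact numpy engine for small 1-D convolutional networks.

Implements exactly the layer set the peptide-window classifiers need:
1-D convolution ('same' or 'valid' padding, via im2col so the inner loop is a
BLAS matmul), max pooling, inverted dropout, a trainable token embedding,
position-wise (time-distributed) dense layers expressed as size-1 convolutions,
global average pooling, and a final dense output. Training uses Adam with
binary cross-entropy on logits. All randomness (initialization, dropout masks,
batch shuffling) flows from explicit numpy Generators, so runs are
reproducible bit-for-bit on a fixed BLAS.

Gradients of every layer are verified against central finite differences in
the test suite.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

__all__ = [
    "Conv1D", "Dense", "Dropout", "Embedding", "GlobalAveragePooling1D",
    "MaxPool1D", "Network", "Adam", "sigmoid", "bce_with_logits",
]


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(z: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy on logits; returns (loss, dloss/dz)."""
    z = z.ravel()
    y = y.ravel().astype(z.dtype)
    # log(1 + e^z) computed stably
    loss = float(np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))))
    grad = (sigmoid(z) - y) / z.size
    return loss, grad.reshape(-1, 1)


class Layer:
    """Base layer: parameter dicts plus forward/backward passes."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


class Conv1D(Layer):
    """1-D convolution over (batch, positions, channels) input.

    'same' padding is asymmetric for even kernel sizes (left ``(k-1)//2``,
    right ``k//2``) so the output always has the input's position count;
    'valid' shrinks it by ``k - 1``. Weights use He-normal initialization
    (suited to the ReLU activation).
    """

    def __init__(self, in_channels: int, filters: int, kernel_size: int,
                 rng: np.random.Generator, padding: str = "same",
                 activation: str = "relu", dtype=np.float32) -> None:
        super().__init__()
        if padding not in ("same", "valid"):
            raise ValueError(f"unknown padding {padding!r}")
        if activation not in ("relu", "linear"):
            raise ValueError(f"unknown activation {activation!r}")
        self.k = kernel_size
        self.in_channels = in_channels
        self.filters = filters
        self.padding = padding
        self.activation = activation
        fan_in = kernel_size * in_channels
        self.params = {
            "W": (rng.standard_normal((fan_in, filters)) * np.sqrt(2.0 / fan_in)
                  ).astype(dtype),
            "b": np.zeros(filters, dtype=dtype),
        }

    def _im2col(self, xp: np.ndarray, L_out: int) -> np.ndarray:
        n = xp.shape[0]
        cols = np.empty((n, L_out, self.k, self.in_channels), dtype=xp.dtype)
        for i in range(self.k):
            cols[:, :, i, :] = xp[:, i:i + L_out, :]
        return cols.reshape(n, L_out, self.k * self.in_channels)

    def forward(self, x, train=False, rng=None):
        n, L, C = x.shape
        if C != self.in_channels:
            raise ValueError(f"expected {self.in_channels} channels, got {C}")
        if self.padding == "same":
            left, right = (self.k - 1) // 2, self.k // 2
            xp = np.pad(x, ((0, 0), (left, right), (0, 0)))
            L_out = L
        else:
            xp, L_out = x, L - self.k + 1
        cols = self._im2col(xp, L_out)
        z = cols @ self.params["W"] + self.params["b"]
        self._cache = (cols, z, (n, L, C))
        return _relu(z) if self.activation == "relu" else z

    def backward(self, dy):
        cols, z, (n, L, C) = self._cache
        dz = dy * (z > 0) if self.activation == "relu" else dy
        L_out = dz.shape[1]
        dz2 = dz.reshape(n * L_out, self.filters)
        self.grads["W"] = cols.reshape(n * L_out, -1).T @ dz2
        self.grads["b"] = dz2.sum(axis=0)
        dcols = (dz2 @ self.params["W"].T).reshape(n, L_out, self.k, C)
        if self.padding == "same":
            left = (self.k - 1) // 2
            Lp = L + self.k - 1
        else:
            left, Lp = 0, L
        dxp = np.zeros((n, Lp, C), dtype=dy.dtype)
        for i in range(self.k):
            dxp[:, i:i + L_out, :] += dcols[:, :, i, :]
        return dxp[:, left:left + L, :] if self.padding == "same" else dxp


class Dense(Layer):
    """Fully connected layer on (batch, features) input."""

    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator, activation: str = "linear",
                 dtype=np.float32) -> None:
        super().__init__()
        self.activation = activation
        scale = np.sqrt(2.0 / in_features) if activation == "relu" else \
            np.sqrt(1.0 / in_features)
        self.params = {
            "W": (rng.standard_normal((in_features, out_features)) * scale
                  ).astype(dtype),
            "b": np.zeros(out_features, dtype=dtype),
        }

    def forward(self, x, train=False, rng=None):
        z = x @ self.params["W"] + self.params["b"]
        self._cache = (x, z)
        return _relu(z) if self.activation == "relu" else z

    def backward(self, dy):
        x, z = self._cache
        dz = dy * (z > 0) if self.activation == "relu" else dy
        self.grads["W"] = x.T @ dz
        self.grads["b"] = dz.sum(axis=0)
        return dz @ self.params["W"].T


class Dropout(Layer):
    """Inverted dropout: active only during training, identity at inference."""

    def __init__(self, rate: float) -> None:
        super().__init__()
        if not 0 <= rate < 1:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate

    def forward(self, x, train=False, rng=None):
        if not train or self.rate == 0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("training-mode dropout requires an rng")
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask.astype(x.dtype)

    def backward(self, dy):
        if self._mask is None:
            return dy
        return dy * self._mask.astype(dy.dtype)


class MaxPool1D(Layer):
    """Max pooling with stride equal to the pool size; trailing remainder dropped."""

    def __init__(self, pool_size: int = 2) -> None:
        super().__init__()
        self.p = pool_size

    def forward(self, x, train=False, rng=None):
        n, L, C = x.shape
        L_out = L // self.p
        xt = x[:, :L_out * self.p, :].reshape(n, L_out, self.p, C)
        self._argmax = xt.argmax(axis=2)
        self._in_shape = (n, L, C)
        return np.take_along_axis(xt, self._argmax[:, :, None, :], axis=2)[:, :, 0, :]

    def backward(self, dy):
        n, L, C = self._in_shape
        L_out = L // self.p
        dxt = np.zeros((n, L_out, self.p, C), dtype=dy.dtype)
        np.put_along_axis(dxt, self._argmax[:, :, None, :], dy[:, :, None, :], axis=2)
        dx = np.zeros((n, L, C), dtype=dy.dtype)
        dx[:, :L_out * self.p, :] = dxt.reshape(n, L_out * self.p, C)
        return dx


class Embedding(Layer):
    """Trainable lookup of integer tokens into dense vectors."""

    def __init__(self, vocab_size: int, dim: int, rng: np.random.Generator,
                 table: np.ndarray | None = None, trainable: bool = True,
                 dtype=np.float32) -> None:
        super().__init__()
        self.vocab_size = vocab_size
        self.trainable = trainable
        if table is not None:
            table = np.asarray(table, dtype=dtype)
            if table.shape != (vocab_size, dim):
                raise ValueError(f"embedding table must be {(vocab_size, dim)}")
            W = table.copy()
        else:
            W = (rng.standard_normal((vocab_size, dim)) * 0.1).astype(dtype)
        self.params = {"W": W}

    def forward(self, x, train=False, rng=None):
        tokens = np.asarray(x)
        if tokens.min() < 0 or tokens.max() >= self.vocab_size:
            raise ValueError("token outside embedding vocabulary")
        self._tokens = tokens
        return self.params["W"][tokens]

    def backward(self, dy):
        dW = np.zeros_like(self.params["W"], dtype=np.float64)
        np.add.at(dW, self._tokens, dy.astype(np.float64))
        self.grads["W"] = dW.astype(self.params["W"].dtype) if self.trainable \
            else np.zeros_like(self.params["W"])
        return np.zeros(self._tokens.shape)  # tokens carry no gradient


class GlobalAveragePooling1D(Layer):
    """Mean over the position axis: (n, L, C) -> (n, C)."""

    def forward(self, x, train=False, rng=None):
        self._L = x.shape[1]
        return x.mean(axis=1)

    def backward(self, dy):
        return np.repeat(dy[:, None, :], self._L, axis=1) / self._L


class Network:
    """A plain sequential stack of layers."""

    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train, rng=rng)
        return x

    def backward(self, dy: np.ndarray) -> None:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)

    def clear_caches(self) -> None:
        """Drop per-batch forward caches (they can dwarf the weights)."""
        for layer in self.layers:
            for attr in ("_cache", "_mask", "_argmax", "_in_shape", "_tokens"):
                if hasattr(layer, attr):
                    delattr(layer, attr)

    def param_items(self) -> Iterator[tuple[Layer, str]]:
        for layer in self.layers:
            for name in layer.params:
                yield layer, name

    def get_weights(self) -> list[np.ndarray]:
        return [layer.params[name].copy() for layer, name in self.param_items()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for (layer, name), w in zip(self.param_items(), weights, strict=True):
            layer.params[name] = w.copy()


class Adam:
    """Adam optimizer over a :class:`Network`'s parameters."""

    def __init__(self, net: Network, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.net = net
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(layer.params[n]) for layer, n in net.param_items()]
        self.v = [np.zeros_like(layer.params[n]) for layer, n in net.param_items()]

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for i, (layer, name) in enumerate(self.net.param_items()):
            g = layer.grads[name]
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / bc1
            vhat = self.v[i] / bc2
            layer.params[name] -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)
                                   ).astype(layer.params[name].dtype)
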