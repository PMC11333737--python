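"""Minimal NumPy neural-network layers with explicit backpropagation.

Only what the per-channel scorer and the feature-fusion comparator need:
valid 1D convolution, ReLU, inverted dropout, max pooling, flatten, dense,
softmax cross-entropy, and Adam.  Inputs are small fixed-length windows
(shape ``(N, L, C)``), so dense NumPy einsums are fast and exactly
reproducible: every source of randomness (initialization, dropout masks,
shuffling) is drawn from a single ``numpy.random.Generator``.
"""

from __future__ import annotations

from typing import Dict, List, Optional

import numpy as np

__all__ = [
    "Conv1D",
    "ReLU",
    "Dropout",
    "MaxPool1D",
    "Flatten",
    "Dense",
    "Sequential",
    "Adam",
    "softmax",
    "softmax_cross_entropy",
]

_EPS = 1e-12


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - np.max(logits, axis=-1, keepdims=True)
    e = np.exp(z)
    return e / np.sum(e, axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy of softmax(logits) against integer labels.

    Returns ``(loss, dlogits)`` with the gradient already averaged over the
    batch.
    """
    probs = softmax(logits)
    n = logits.shape[0]
    loss = float(-np.mean(np.log(probs[np.arange(n), labels] + _EPS)))
    dlogits = probs.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return loss, dlogits / n


class Layer:
    """Base layer: parameter dict plus matching gradient dict."""

    def __init__(self):
        self.params: Dict[str, np.ndarray] = {}
        self.grads: Dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = False,
                rng: Optional[np.random.Generator] = None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv1D(Layer):
    """Valid (unpadded) 1D convolution over (N, L, C_in) -> (N, L-k+1, C_out)."""

    def __init__(self, kernel_size: int, in_channels: int, out_channels: int,
                 rng: np.random.Generator):
        super().__init__()
        self.kernel_size = kernel_size
        fan_in = kernel_size * in_channels
        fan_out = kernel_size * out_channels
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        self.params["W"] = rng.uniform(-limit, limit, (kernel_size, in_channels, out_channels))
        self.params["b"] = np.zeros(out_channels)

    def forward(self, x, train=False, rng=None):
        if x.shape[1] < self.kernel_size:
            raise ValueError(
                f"input length {x.shape[1]} shorter than kernel {self.kernel_size}"
            )
        windows = np.lib.stride_tricks.sliding_window_view(x, self.kernel_size, axis=1)
        # windows: (N, L_out, C_in, k) -> reorder to (N, L_out, k, C_in)
        self._windows = np.ascontiguousarray(windows.transpose(0, 1, 3, 2))
        self._in_shape = x.shape
        return np.einsum("nlkc,kco->nlo", self._windows, self.params["W"]) + self.params["b"]

    def backward(self, dout):
        W = self.params["W"]
        self.grads["W"] = np.einsum("nlkc,nlo->kco", self._windows, dout)
        self.grads["b"] = dout.sum(axis=(0, 1))
        dx = np.zeros(self._in_shape)
        L_out = dout.shape[1]
        for j in range(self.kernel_size):
            dx[:, j:j + L_out, :] += dout @ W[j].T
        return dx


class ReLU(Layer):
    def forward(self, x, train=False, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class Dropout(Layer):
    """Inverted dropout: identity at inference time."""

    def __init__(self, rate: float):
        super().__init__()
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def forward(self, x, train=False, rng=None):
        if not train or self.rate == 0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("training-mode dropout needs an rng")
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class MaxPool1D(Layer):
    """Non-overlapping max pooling (window = stride); trailing remainder dropped."""

    def __init__(self, stride: int = 2):
        super().__init__()
        self.stride = stride

    def forward(self, x, train=False, rng=None):
        n, L, c = x.shape
        L_out = L // self.stride
        x_trim = x[:, :L_out * self.stride, :].reshape(n, L_out, self.stride, c)
        self._argmax = np.argmax(x_trim, axis=2)
        self._in_shape = x.shape
        return np.max(x_trim, axis=2)

    def backward(self, dout):
        n, L_out, c = dout.shape
        dx = np.zeros((n, L_out, self.stride, c))
        ni, li, ci = np.indices((n, L_out, c))
        dx[ni, li, self._argmax, ci] = dout
        full = np.zeros(self._in_shape)
        full[:, :L_out * self.stride, :] = dx.reshape(n, L_out * self.stride, c)
        return full


class Flatten(Layer):
    def forward(self, x, train=False, rng=None):
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._in_shape)


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        limit = np.sqrt(6.0 / (in_features + out_features))
        self.params["W"] = rng.uniform(-limit, limit, (in_features, out_features))
        self.params["b"] = np.zeros(out_features)

    def forward(self, x, train=False, rng=None):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout):
        self.grads["W"] = self._x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["W"].T


class Sequential:
    def __init__(self, layers: List[Layer]):
        self.layers = layers

    def forward(self, x, train=False, rng=None):
        for layer in self.layers:
            x = layer.forward(x, train=train, rng=rng)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def parameters(self):
        """Yield ``(key, layer, name)`` for every trainable array."""
        for i, layer in enumerate(self.layers):
            for name in layer.params:
                yield (i, name), layer, name

    def n_parameters(self) -> int:
        return sum(layer.params[name].size for _, layer, name in self.parameters())


class Adam:
    """Adam with the usual bias-corrected moment estimates."""

    def __init__(self, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._m: Dict = {}
        self._v: Dict = {}

    def step(self, model: Sequential):
        self.t += 1
        for key, layer, name in model.parameters():
            g = layer.grads.get(name)
            if g is None:
                continue
            m = self._m.setdefault(key, np.zeros_like(g))
            v = self._v.setdefault(key, np.zeros_like(g))
            m[:] = self.beta1 * m + (1 - self.beta1) * g
            v[:] = self.beta2 * v + (1 - self.beta2) * g * g
            m_hat = m / (1 - self.beta1 ** self.t)
            v_hat = v / (1 - self.beta2 ** self.t)
            layer.params[name] -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
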