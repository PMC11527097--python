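"""Minimal dense/sparse neural-network primitives (internal).

Reverse-mode gradients are written by hand for the handful of layer types the
package needs: affine maps, graph convolutions against a fixed symmetric
normalized adjacency, elementwise activations, and inverted dropout.  All
training is full-batch, so a layer may cache its forward inputs and the whole
stack is bit-deterministic for a fixed seed (a single BLAS thread evaluates
the same operations in the same order on every run).
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp


class Parameter:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=float)
        self.grad = np.zeros_like(self.value)


def glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class Layer:
    def parameters(self) -> list[Parameter]:
        return []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Linear(Layer):
    """Affine map y = x W + b, applied row-wise."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, bias: bool = True):
        self.W = Parameter(glorot_uniform(rng, d_in, d_out))
        self.b = Parameter(np.zeros(d_out)) if bias else None

    def parameters(self):
        return [self.W] + ([self.b] if self.b is not None else [])

    def forward(self, x, training):
        self._x = x
        y = x @ self.W.value
        if self.b is not None:
            y = y + self.b.value
        return y

    def backward(self, dout):
        self.W.grad += self._x.T @ dout
        if self.b is not None:
            self.b.grad += dout.sum(axis=0)
        return dout @ self.W.value.T


class GraphConv(Layer):
    """Graph convolution y = A_norm (x W) with a fixed symmetric A_norm, no bias."""

    def __init__(self, d_in: int, d_out: int, a_norm: sp.spmatrix, rng: np.random.Generator):
        self.W = Parameter(glorot_uniform(rng, d_in, d_out))
        self.a_norm = sp.csr_matrix(a_norm)

    def parameters(self):
        return [self.W]

    def forward(self, x, training):
        self._x = x
        return self.a_norm @ (x @ self.W.value)

    def backward(self, dout):
        # A_norm is symmetric, so A^T dout = A dout
        h = self.a_norm @ dout
        self.W.grad += self._x.T @ h
        return h @ self.W.value.T


_ACTIVATIONS = {
    "relu": (lambda x: np.maximum(x, 0.0), lambda x, y: (x > 0).astype(float)),
    "tanh": (np.tanh, lambda x, y: 1.0 - y * y),
    "identity": (lambda x: x, lambda x, y: np.ones_like(x)),
}


class Activation(Layer):
    def __init__(self, name: str = "relu"):
        if name not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {name!r}; choose from {sorted(_ACTIVATIONS)}")
        self.name = name
        self._f, self._df = _ACTIVATIONS[name]

    def forward(self, x, training):
        self._x = x
        self._y = self._f(x)
        return self._y

    def backward(self, dout):
        return dout * self._df(self._x, self._y)


class Dropout(Layer):
    """Inverted dropout; identity when not training or rate == 0."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng
        self._mask = None

    def forward(self, x, training):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dout):
        if self._mask is None:
            return dout
        return dout * self._mask


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def parameters(self):
        out: list[Parameter] = []
        for layer in self.layers:
            out.extend(layer.parameters())
        return out

    def forward(self, x, training=False):
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, labels: np.ndarray, mask_idx: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """Mean cross-entropy over the rows in ``mask_idx`` only.

    Returns ``(loss, dlogits, probs)``; ``dlogits`` is zero outside the mask,
    so gradients can never depend on labels of unmasked (e.g. test) rows.
    """
    probs = softmax(logits)
    mask_idx = np.asarray(mask_idx, dtype=int)
    m = mask_idx.size
    if m == 0:
        raise ValueError("empty loss mask")
    picked = probs[mask_idx, labels[mask_idx]]
    loss = float(-np.mean(np.log(np.clip(picked, 1e-300, None))))
    dlogits = np.zeros_like(probs)
    dlogits[mask_idx] = probs[mask_idx]
    dlogits[mask_idx, labels[mask_idx]] -= 1.0
    dlogits[mask_idx] /= m
    return loss, dlogits, probs


def softmax_backward(probs: np.ndarray, dprobs: np.ndarray) -> np.ndarray:
    """Gradient through a row-wise softmax given d(loss)/d(probs)."""
    inner = (dprobs * probs).sum(axis=1, keepdims=True)
    return probs * (dprobs - inner)


class Adam:
    """Standard Adam with bias correction."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * p.grad
            v *= self.beta2
            v += (1.0 - self.beta2) * p.grad * p.grad
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
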