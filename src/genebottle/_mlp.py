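"""Minimal dense-MLP engine: forward, backprop, SGD-with-momentum and Adam.

Shared by g-networks (scalar regression heads) and desk-scale p-networks
(softmax classifiers). Everything is plain NumPy; nets at this scale are a
few thousand parameters, so vectorised batches are more than fast enough.
"""

from __future__ import annotations

from typing import List, Optional, Sequence, Tuple

import numpy as np

__all__ = ["init_layers", "forward", "mse_loss_grads", "softmax_xent_grads",
           "SGDMomentum", "Adam", "glorot_uniform"]


def glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def init_layers(widths: Sequence[int], rng: np.random.Generator,
                bias_layers: Optional[Sequence[bool]] = None) -> list:
    """[(W, b_or_None), ...] for a dense stack; scaled-uniform (Glorot) init."""
    if bias_layers is None:
        bias_layers = [True] * (len(widths) - 1)
    layers = []
    for k in range(len(widths) - 1):
        W = glorot_uniform(rng, widths[k], widths[k + 1])
        b = np.zeros(widths[k + 1]) if bias_layers[k] else None
        layers.append((W, b))
    return layers


def _act(z: np.ndarray, kind: str) -> np.ndarray:
    if kind == "relu":
        return np.maximum(z, 0.0)
    if kind == "tanh":
        return np.tanh(z)
    if kind == "identity":
        return z
    raise ValueError(f"unknown activation {kind!r}")


def _act_grad(z: np.ndarray, a: np.ndarray, kind: str) -> np.ndarray:
    if kind == "relu":
        return (z > 0.0).astype(z.dtype)
    if kind == "tanh":
        return 1.0 - a * a
    if kind == "identity":
        return np.ones_like(z)
    raise ValueError(f"unknown activation {kind!r}")


def forward(layers: list, X: np.ndarray, hidden_activation: str = "relu",
            output_activation: str = "identity",
            dropout: Optional[Sequence[float]] = None,
            rng: Optional[np.random.Generator] = None,
            return_cache: bool = False):
    """Batch forward pass. ``dropout[k]`` is the drop probability applied to
    the activation of layer k (inverted dropout; active only when ``rng`` is
    given, i.e. at training time)."""
    a = np.asarray(X, dtype=np.float64)
    cache = []
    n_layers = len(layers)
    for k, (W, b) in enumerate(layers):
        z = a @ W
        if b is not None:
            z = z + b
        kind = output_activation if k == n_layers - 1 else hidden_activation
        out = _act(z, kind)
        mask = None
        if dropout is not None and rng is not None and k < n_layers - 1:
            p = dropout[k] if k < len(dropout) else 0.0
            if p > 0.0:
                mask = (rng.random(out.shape) >= p) / (1.0 - p)
                out = out * mask
        cache.append((a, z, out, kind, mask))
        a = out
    return (a, cache) if return_cache else a


def _backprop(layers: list, cache: list, delta: np.ndarray) -> list:
    """Gradients from an output-side error signal dL/d(pre-activation of last
    layer already folded in by the caller via ``delta`` = dL/d(output))."""
    grads = [None] * len(layers)
    for k in range(len(layers) - 1, -1, -1):
        a_in, z, out, kind, mask = cache[k]
        if mask is not None:
            delta = delta * mask
        dz = delta * _act_grad(z, out if mask is None else _act(z, kind), kind)
        W, b = layers[k]
        gW = a_in.T @ dz
        gb = dz.sum(axis=0) if b is not None else None
        grads[k] = (gW, gb)
        if k > 0:
            delta = dz @ W.T
    return grads


def mse_loss_grads(layers: list, X: np.ndarray, y: np.ndarray,
                   hidden_activation: str = "relu") -> Tuple[float, list]:
    """Mean-squared-error loss and parameter gradients for a regression head."""
    pred, cache = forward(layers, X, hidden_activation, "identity",
                          return_cache=True)
    pred = pred.reshape(-1)
    y = np.asarray(y, dtype=np.float64).reshape(-1)
    resid = pred - y
    loss = float(np.mean(resid ** 2))
    delta = (2.0 / y.size) * resid[:, None]
    return loss, _backprop(layers, cache, delta)


def softmax_xent_grads(layers: list, X: np.ndarray, labels: np.ndarray,
                       hidden_activation: str = "relu",
                       dropout=None, rng=None) -> Tuple[float, list]:
    """Mean cross-entropy of softmax(logits) against integer labels."""
    logits, cache = forward(layers, X, hidden_activation, "identity",
                            dropout=dropout, rng=rng, return_cache=True)
    logits = logits - logits.max(axis=1, keepdims=True)
    expz = np.exp(logits)
    probs = expz / expz.sum(axis=1, keepdims=True)
    n = len(labels)
    loss = float(-np.mean(np.log(probs[np.arange(n), labels] + 1e-300)))
    delta = probs.copy()
    delta[np.arange(n), labels] -= 1.0
    delta /= n
    return loss, _backprop(layers, cache, delta)


class SGDMomentum:
    """Classical momentum SGD: v ← μv − η∇; θ ← θ + v."""

    def __init__(self, lr: float = 0.05, momentum: float = 0.9):
        self.lr = lr
        self.momentum = momentum
        self._v = None

    def step(self, layers: list, grads: list) -> list:
        if self._v is None:
            self._v = [(np.zeros_like(W), None if b is None else np.zeros_like(b))
                       for W, b in layers]
        new_layers = []
        for k, ((W, b), (gW, gb)) in enumerate(zip(layers, grads)):
            vW, vb = self._v[k]
            vW = self.momentum * vW - self.lr * gW
            W = W + vW
            if b is not None:
                vb = self.momentum * vb - self.lr * gb
                b = b + vb
            self._v[k] = (vW, vb)
            new_layers.append((W, b))
        return new_layers


class Adam:
    """Adaptive-moment estimation with the standard bias correction."""

    def __init__(self, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self._m = None
        self._v = None
        self._t = 0

    def _zeros(self, layers):
        return [(np.zeros_like(W), None if b is None else np.zeros_like(b))
                for W, b in layers]

    def step(self, layers: list, grads: list) -> list:
        if self._m is None:
            self._m, self._v = self._zeros(layers), self._zeros(layers)
        self._t += 1
        b1, b2 = self.beta1, self.beta2
        c1 = 1.0 - b1 ** self._t
        c2 = 1.0 - b2 ** self._t
        new_layers = []
        for k, ((W, b), (gW, gb)) in enumerate(zip(layers, grads)):
            mW, mb = self._m[k]
            vW, vb = self._v[k]
            mW = b1 * mW + (1 - b1) * gW
            vW = b2 * vW + (1 - b2) * gW * gW
            W = W - self.lr * (mW / c1) / (np.sqrt(vW / c2) + self.eps)
            if b is not None:
                mb = b1 * mb + (1 - b1) * gb
                vb = b2 * vb + (1 - b2) * gb * gb
                b = b - self.lr * (mb / c1) / (np.sqrt(vb / c2) + self.eps)
            self._m[k] = (mW, mb)
            self._v[k] = (vW, vb)
            new_layers.append((W, b))
        return new_layers
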