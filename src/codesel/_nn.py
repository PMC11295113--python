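"""Minimal feed-forward network core (numpy, manual backprop, Adam).

The selection and evaluation networks in this package are small dense
models on modest matrices, so they are implemented directly on numpy
arrays: dense layers with leaky-ReLU hidden activations, sigmoid outputs
trained by (optionally per-feature weighted) binary cross-entropy, or
linear outputs trained by squared error, inverted dropout, and Adam.
Everything is driven by an explicit ``numpy.random.Generator`` so runs
are reproducible bit-for-bit.
"""

from __future__ import annotations

import numpy as np

LEAKY_SLOPE = 0.01
_EPS = 1e-7


def leaky_relu(x: np.ndarray) -> np.ndarray:
    return np.where(x > 0, x, LEAKY_SLOPE * x)


def leaky_relu_grad(x: np.ndarray) -> np.ndarray:
    return np.where(x > 0, 1.0, LEAKY_SLOPE)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def bce(pred: np.ndarray, target: np.ndarray, weights: np.ndarray | None = None) -> float:
    """Mean binary cross-entropy; optional per-feature weights normalized
    by their sum so the loss scale is comparable across weightings."""
    p = np.clip(pred, _EPS, 1.0 - _EPS)
    per_elem = -(target * np.log(p) + (1.0 - target) * np.log(1.0 - p))
    if weights is None:
        return float(per_elem.mean())
    w = np.asarray(weights, dtype=float)
    return float((per_elem * w).sum(axis=-1).mean() / w.sum())


class Adam:
    """Adam optimizer over a flat list of parameter arrays (updates in place)."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


class MLP:
    """Dense feed-forward net: leaky-ReLU hidden layers, sigmoid or
    linear output.  ``forward`` caches activations for ``backward``."""

    def __init__(self, sizes: list[int], rng: np.random.Generator,
                 out_activation: str = "sigmoid",
                 init_scale: float | None = None):
        """``init_scale=None`` gives He initialization; a float gives
        ``normal(0, init_scale)`` on every weight (used where weight
        magnitudes are read out as scores and must start near zero)."""
        if out_activation not in ("sigmoid", "linear"):
            raise ValueError(out_activation)
        self.sizes = list(sizes)
        self.out_activation = out_activation
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            scale = np.sqrt(2.0 / fan_in) if init_scale is None else init_scale
            self.weights.append(rng.normal(0.0, scale, size=(fan_in, fan_out)))
            self.biases.append(np.zeros(fan_out))

    @property
    def params(self) -> list[np.ndarray]:
        out: list[np.ndarray] = []
        for w, b in zip(self.weights, self.biases):
            out += [w, b]
        return out

    def forward(self, x: np.ndarray, dropout: float = 0.0,
                rng: np.random.Generator | None = None,
                train: bool = True) -> tuple[np.ndarray, dict]:
        """Returns (output, cache).  Dropout (inverted) is applied to
        hidden activations only when ``train`` and ``dropout > 0``."""
        cache: dict = {"inputs": [x], "pre": [], "masks": []}
        h = x
        n_layers = len(self.weights)
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            z = h @ w + b
            cache["pre"].append(z)
            if i < n_layers - 1:
                h = leaky_relu(z)
                if train and dropout > 0.0:
                    if rng is None:
                        raise ValueError("dropout requires an rng")
                    mask = (rng.random(h.shape) >= dropout) / (1.0 - dropout)
                    h = h * mask
                    cache["masks"].append(mask)
                else:
                    cache["masks"].append(None)
                cache["inputs"].append(h)
            else:
                out = sigmoid(z) if self.out_activation == "sigmoid" else z
        cache["out"] = out
        return out, cache

    def backward(self, cache: dict, dpre_out: np.ndarray) -> tuple[list[np.ndarray], np.ndarray]:
        """Backprop from the gradient w.r.t. the output PRE-activation.

        For sigmoid + BCE this is ``(pred - target) * w / (B * sum_w)``;
        for linear + squared error ``(pred - target) / B`` (times any
        scaling).  Returns (grads aligned with ``params``, dLoss/dinput).
        """
        grads_w: list[np.ndarray] = [np.empty(0)] * len(self.weights)
        grads_b: list[np.ndarray] = [np.empty(0)] * len(self.biases)
        delta = dpre_out
        for i in range(len(self.weights) - 1, -1, -1):
            h_in = cache["inputs"][i]
            grads_w[i] = h_in.T @ delta
            grads_b[i] = delta.sum(axis=0)
            if i > 0:
                dh = delta @ self.weights[i].T
                mask = cache["masks"][i - 1]
                if mask is not None:
                    dh = dh * mask
                delta = dh * leaky_relu_grad(cache["pre"][i - 1])
            else:
                dx = delta @ self.weights[0].T
        out: list[np.ndarray] = []
        for gw, gb in zip(grads_w, grads_b):
            out += [gw, gb]
        return out, dx

    def predict(self, x: np.ndarray) -> np.ndarray:
        out, _ = self.forward(x, dropout=0.0, train=False)
        return out


def minibatches(n: int, batch_size: int, rng: np.random.Generator):
    """Yield shuffled index arrays covering ``range(n)`` once."""
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start:start + batch_size]
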