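"""Minimal feed-forward network trained with mini-batch SGD.

Implements exactly the classifier this pipeline needs: fully connected
hidden layers with a choice of rectifier / tanh / sigmoid activations,
inverted dropout after each hidden layer, a single sigmoid output unit, and
binary cross-entropy minimized by stochastic gradient descent with momentum.
Weights start from N(0, sd²) and biases from U(-1, 0) (or zero), matching
the initialization the pipeline prescribes. Everything is plain numpy; all
randomness flows through one ``numpy.random.Generator``.
"""

from __future__ import annotations

import numpy as np

from .exceptions import ParameterError


def relu(x: np.ndarray) -> np.ndarray:
    """Rectifier: the positive part of the argument, max(x, 0)."""
    return np.maximum(x, 0.0)


def sigmoid(x: np.ndarray) -> np.ndarray:
    """Numerically stable logistic function 1 / (1 + exp(-x))."""
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


_ACTIVATIONS = {
    "relu": (relu, lambda a: (a > 0).astype(float)),
    "tanh": (np.tanh, lambda a: 1.0 - a**2),
    "sigmoid": (sigmoid, lambda a: a * (1.0 - a)),
}


class FeedForwardNet:
    """Hidden layers -> dropout -> ... -> sigmoid output scalar."""

    def __init__(
        self,
        input_dim: int,
        hidden_sizes: tuple[int, ...],
        activation: str = "relu",
        dropout: float = 0.5,
        weight_sd: float = 0.05,
        bias_init: str = "uniform_neg",
        rng: np.random.Generator | None = None,
    ):
        if activation not in _ACTIVATIONS:
            raise ParameterError(f"unknown activation {activation!r}")
        if not 0 <= dropout < 1:
            raise ParameterError("dropout must be in [0, 1)")
        if bias_init not in ("uniform_neg", "zeros"):
            raise ParameterError(f"unknown bias_init {bias_init!r}")
        rng = rng or np.random.default_rng()
        self.activation = activation
        self.dropout = dropout
        self.input_dim = input_dim
        sizes = [input_dim, *hidden_sizes, 1]
        self.W = [
            rng.normal(0.0, weight_sd, size=(sizes[k], sizes[k + 1]))
            for k in range(len(sizes) - 1)
        ]
        if bias_init == "uniform_neg":
            self.b = [rng.uniform(-1.0, 0.0, size=sizes[k + 1]) for k in range(len(sizes) - 1)]
        else:
            self.b = [np.zeros(sizes[k + 1]) for k in range(len(sizes) - 1)]
        self._vW = [np.zeros_like(w) for w in self.W]
        self._vb = [np.zeros_like(b) for b in self.b]

    # ---- inference -------------------------------------------------------

    def forward(self, X: np.ndarray, train_rng: np.random.Generator | None = None):
        """Return (output probabilities, cache). Dropout only when a rng is given."""
        act, _ = _ACTIVATIONS[self.activation]
        a = X
        activations = [X]
        masks: list[np.ndarray | None] = []
        n_hidden = len(self.W) - 1
        for k in range(n_hidden):
            a = act(a @ self.W[k] + self.b[k])
            if train_rng is not None and self.dropout > 0:
                mask = (train_rng.random(a.shape) >= self.dropout) / (1.0 - self.dropout)
                a = a * mask
                masks.append(mask)
            else:
                masks.append(None)
            activations.append(a)
        z = a @ self.W[-1] + self.b[-1]
        p = sigmoid(z).ravel()
        return p, (activations, masks)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Deterministic probabilities (dropout disabled)."""
        return self.forward(X)[0]

    # ---- training --------------------------------------------------------

    def _backward(self, p: np.ndarray, y: np.ndarray, cache) -> list[tuple[np.ndarray, np.ndarray]]:
        activations, masks = cache
        _, act_grad = _ACTIVATIONS[self.activation]
        n = len(y)
        # BCE + sigmoid: gradient at the output pre-activation is (p - y)/n
        delta = ((p - y) / n)[:, None]
        grads: list[tuple[np.ndarray, np.ndarray]] = []
        for k in range(len(self.W) - 1, -1, -1):
            a_prev = activations[k]
            gW = a_prev.T @ delta
            gb = delta.sum(axis=0)
            grads.append((gW, gb))
            if k > 0:
                delta = delta @ self.W[k].T
                if masks[k - 1] is not None:
                    delta = delta * masks[k - 1]
                delta = delta * act_grad(activations[k])
        grads.reverse()
        return grads

    def train_epoch(
        self,
        X: np.ndarray,
        y: np.ndarray,
        lr: float,
        momentum: float,
        batch_size: int,
        rng: np.random.Generator,
    ) -> float:
        """One shuffled pass over the data; returns the mean batch BCE loss."""
        idx = rng.permutation(len(y))
        losses = []
        for start in range(0, len(y), batch_size):
            sel = idx[start : start + batch_size]
            Xb, yb = X[sel], y[sel]
            p, cache = self.forward(Xb, train_rng=rng)
            eps = 1e-12
            losses.append(
                float(-np.mean(yb * np.log(p + eps) + (1 - yb) * np.log(1 - p + eps)))
            )
            for k, (gW, gb) in enumerate(self._backward(p, yb, cache)):
                self._vW[k] = momentum * self._vW[k] - lr * gW
                self._vb[k] = momentum * self._vb[k] - lr * gb
                self.W[k] += self._vW[k]
                self.b[k] += self._vb[k]
        return float(np.mean(losses))
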