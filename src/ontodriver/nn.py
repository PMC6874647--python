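"""Small fully connected binary classifier: ReLU hidden layers, a sigmoid
output unit, binary cross-entropy loss, RMSprop updates.  Numpy only;
deterministic for a fixed seed."""

from __future__ import annotations

import numpy as np

__all__ = ["FeedforwardNet"]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30.0, 30.0)))


class FeedforwardNet:
    """Binary feedforward classifier.

    Parameters
    ----------
    n_features
        Input width.
    hidden_layers
        Widths of the ReLU hidden layers.
    learning_rate, rho, eps
        RMSprop parameters (cache = rho*cache + (1-rho)*g**2;
        step = lr*g/(sqrt(cache)+eps)).
    """

    def __init__(
        self,
        n_features: int,
        hidden_layers: tuple[int, ...] = (128, 64),
        epochs: int = 150,
        batch_size: int = 16,
        learning_rate: float = 1e-3,
        rho: float = 0.9,
        eps: float = 1e-8,
        seed: int = 0,
    ) -> None:
        self.hidden_layers = tuple(hidden_layers)
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.rho = rho
        self.eps = eps
        self.seed = seed
        rng = np.random.default_rng(seed)
        widths = (n_features, *self.hidden_layers, 1)
        self.weights = [
            rng.normal(0.0, np.sqrt(2.0 / widths[i]), size=(widths[i], widths[i + 1]))
            for i in range(len(widths) - 1)
        ]
        self.biases = [np.zeros(w) for w in widths[1:]]
        self._cache_w = [np.zeros_like(w) for w in self.weights]
        self._cache_b = [np.zeros_like(b) for b in self.biases]
        self._rng = rng

    def _forward(self, X: np.ndarray) -> tuple[list[np.ndarray], np.ndarray]:
        activations = [X]
        for W, b in zip(self.weights[:-1], self.biases[:-1]):
            activations.append(np.maximum(0.0, activations[-1] @ W + b))
        logits = activations[-1] @ self.weights[-1] + self.biases[-1]
        return activations, logits[:, 0]

    def fit(self, X: np.ndarray, y: np.ndarray) -> "FeedforwardNet":
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        n = X.shape[0]
        for _ in range(self.epochs):
            order = self._rng.permutation(n)
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                self._step(X[idx], y[idx])
        return self

    def _step(self, Xb: np.ndarray, yb: np.ndarray) -> None:
        activations, logits = self._forward(Xb)
        # dL/dlogit for sigmoid + cross-entropy
        delta = (_sigmoid(logits) - yb)[:, None] / Xb.shape[0]
        grads_w: list[np.ndarray] = []
        grads_b: list[np.ndarray] = []
        for layer in range(len(self.weights) - 1, -1, -1):
            grads_w.append(activations[layer].T @ delta)
            grads_b.append(delta.sum(axis=0))
            if layer > 0:
                delta = (delta @ self.weights[layer].T) * (activations[layer] > 0)
        grads_w.reverse()
        grads_b.reverse()
        for i, (gw, gb) in enumerate(zip(grads_w, grads_b)):
            self._cache_w[i] = self.rho * self._cache_w[i] + (1 - self.rho) * gw**2
            self._cache_b[i] = self.rho * self._cache_b[i] + (1 - self.rho) * gb**2
            self.weights[i] -= self.learning_rate * gw / (np.sqrt(self._cache_w[i]) + self.eps)
            self.biases[i] -= self.learning_rate * gb / (np.sqrt(self._cache_b[i]) + self.eps)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """P(driver) per row."""
        _, logits = self._forward(np.asarray(X, dtype=np.float64))
        return _sigmoid(logits)
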