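"""Minimal seeded feed-forward network (dense layers, ReLU, dropout, Adam).

Covers the three network shapes the pipeline needs — feed-forward base
learners (sigmoid/linear head, BCE/MSE loss), hourglass autoencoders
(multi-output ReLU head, MSE loss) and the shallow prediction-space stacker —
with fully deterministic behaviour under a fixed seed.  Dropout is inverted
dropout, active only during training; prediction is deterministic.
"""

from __future__ import annotations

import numpy as np

__all__ = ["FeedForwardNet"]


def _relu(z):
    return np.maximum(z, 0.0)


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))


class FeedForwardNet:
    """Dense multilayer perceptron trained with Adam.

    Parameters
    ----------
    layer_widths : sequence of int
        Full width sequence including input and output, e.g. ``[F, 10, 10, 1]``.
    out_activation : {"linear", "sigmoid", "relu"}
    loss : {"mse", "bce"}
        ``bce`` requires a sigmoid output.
    dropout : float in [0, 1)
        Rate applied after every hidden activation during training.
    learning_rate, epochs, batch_size, seed
        Optimization settings; ``seed`` drives init, shuffling and dropout.
    """

    def __init__(self, layer_widths, *, out_activation="linear", loss="mse",
                 dropout=0.0, learning_rate=1e-4, epochs=125, batch_size=32,
                 seed=0):
        if len(layer_widths) < 2:
            raise ValueError("need at least input and output widths")
        if not 0.0 <= dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if loss == "bce" and out_activation != "sigmoid":
            raise ValueError("bce loss requires a sigmoid output")
        if out_activation not in ("linear", "sigmoid", "relu"):
            raise ValueError(f"unknown output activation: {out_activation!r}")
        self.layer_widths = [int(w) for w in layer_widths]
        self.out_activation = out_activation
        self.loss = loss
        self.dropout = float(dropout)
        self.learning_rate = float(learning_rate)
        self.epochs = int(epochs)
        self.batch_size = int(batch_size)
        self.seed = int(seed)
        self.loss_curve_: list[float] = []
        self._init_params()

    def _init_params(self):
        rng = np.random.default_rng(self.seed)
        self.W, self.b = [], []
        for fan_in, fan_out in zip(self.layer_widths[:-1], self.layer_widths[1:]):
            scale = np.sqrt(2.0 / fan_in)  # He init for ReLU stacks
            self.W.append(rng.normal(0.0, scale, size=(fan_in, fan_out)))
            self.b.append(np.zeros(fan_out))
        self._adam_m = [np.zeros_like(w) for w in self.W + self.b]
        self._adam_v = [np.zeros_like(w) for w in self.W + self.b]
        self._adam_t = 0

    # ------------------------------------------------------------------ forward

    def _forward(self, X, rng=None):
        """Returns (activations list, pre-activations list, dropout masks)."""
        a, acts, zs, masks = X, [X], [], []
        n_layers = len(self.W)
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            z = a @ W + b
            zs.append(z)
            if i < n_layers - 1:
                a = _relu(z)
                if rng is not None and self.dropout > 0.0:
                    mask = (rng.random(a.shape) >= self.dropout) / (1.0 - self.dropout)
                    a = a * mask
                    masks.append(mask)
                else:
                    masks.append(None)
            else:
                if self.out_activation == "sigmoid":
                    a = _sigmoid(z)
                elif self.out_activation == "relu":
                    a = _relu(z)
                else:
                    a = z
            acts.append(a)
        return acts, zs, masks

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        out = self._forward(X)[0][-1]
        return out[:, 0] if out.shape[1] == 1 else out

    def hidden_activations(self, X, layer: int) -> np.ndarray:
        """Post-ReLU activations of hidden layer ``layer`` (0-based), no dropout."""
        X = np.asarray(X, dtype=float)
        a = X
        for i in range(layer + 1):
            a = _relu(a @ self.W[i] + self.b[i])
        return a

    # ----------------------------------------------------------------- training

    def _loss_value(self, pred, Y):
        if self.loss == "bce":
            p = np.clip(pred, 1e-12, 1 - 1e-12)
            return float(-np.mean(Y * np.log(p) + (1 - Y) * np.log(1 - p)))
        return float(np.mean((pred - Y) ** 2))

    def _output_delta(self, pred, Y, z_out):
        n = pred.shape[0]
        if self.loss == "bce":  # sigmoid + BCE: combined gradient
            return (pred - Y) / n
        g = 2.0 * (pred - Y) / (n * pred.shape[1])
        if self.out_activation == "sigmoid":
            g = g * pred * (1.0 - pred)
        elif self.out_activation == "relu":
            g = g * (z_out > 0)
        return g

    def _adam_step(self, grads):
        self._adam_t += 1
        lr, b1, b2, eps = self.learning_rate, 0.9, 0.999, 1e-8
        params = self.W + self.b
        for i, (p, g) in enumerate(zip(params, grads)):
            self._adam_m[i] = b1 * self._adam_m[i] + (1 - b1) * g
            self._adam_v[i] = b2 * self._adam_v[i] + (1 - b2) * g * g
            m_hat = self._adam_m[i] / (1 - b1**self._adam_t)
            v_hat = self._adam_v[i] / (1 - b2**self._adam_t)
            p -= lr * m_hat / (np.sqrt(v_hat) + eps)

    def fit(self, X, Y):
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        if X.shape[1] != self.layer_widths[0]:
            raise ValueError(
                f"feature width {X.shape[1]} != input width {self.layer_widths[0]}")
        rng = np.random.default_rng(self.seed + 1)
        n = X.shape[0]
        self.loss_curve_ = []
        for epoch in range(self.epochs):
            order = rng.permutation(n)
            epoch_losses = []
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                xb, yb = X[idx], Y[idx]
                acts, zs, masks = self._forward(xb, rng=rng)
                pred = acts[-1]
                epoch_losses.append(self._loss_value(pred, yb))
                delta = self._output_delta(pred, yb, zs[-1])
                gW = [None] * len(self.W)
                gb = [None] * len(self.b)
                for layer in range(len(self.W) - 1, -1, -1):
                    gW[layer] = acts[layer].T @ delta
                    gb[layer] = delta.sum(axis=0)
                    if layer > 0:
                        delta = delta @ self.W[layer].T
                        if masks[layer - 1] is not None:
                            delta = delta * masks[layer - 1]
                        delta = delta * (zs[layer - 1] > 0)
                self._adam_step(gW + gb)
            loss = float(np.mean(epoch_losses))
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}")
            self.loss_curve_.append(loss)
        return self
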