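"""Minimal deterministic feed-forward regressor in numpy.

Fully connected net with a single linear output unit, trained by mini-batch
SGD with momentum (or Adam) on Huber or squared loss, with inverted dropout
and early stopping on a held-out validation split.  Everything is driven by
one :class:`numpy.random.Generator`, so training is bit-reproducible on a
single thread for a given seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["FeedForwardNet", "TrainingFailure"]

_HUBER_DELTA = 1.0  # years; transition between quadratic and linear regime


class TrainingFailure(RuntimeError):
    """Loss became non-finite during optimisation."""


def _act(name: str, z: np.ndarray) -> np.ndarray:
    if name == "relu":
        return np.maximum(z, 0.0)
    if name == "tanh":
        return np.tanh(z)
    raise ValueError(f"unknown activation {name!r}")


def _act_grad(name: str, z: np.ndarray, a: np.ndarray) -> np.ndarray:
    if name == "relu":
        return (z > 0).astype(z.dtype)
    return 1.0 - a * a  # tanh


@dataclass
class FeedForwardNet:
    weights: list = field(default_factory=list)
    biases: list = field(default_factory=list)
    activation: str = "relu"

    @classmethod
    def init(cls, n_inputs: int, hidden: list[int], activation: str, rng: np.random.Generator):
        sizes = [n_inputs] + list(hidden) + [1]
        net = cls(activation=activation)
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            if activation == "relu":
                scale = np.sqrt(2.0 / fan_in)  # He
            else:
                scale = np.sqrt(1.0 / fan_in)  # Lecun/Glorot-ish for tanh
            net.weights.append(rng.normal(0.0, scale, size=(fan_in, fan_out)))
            net.biases.append(np.zeros(fan_out))
        return net

    def forward(self, X: np.ndarray) -> np.ndarray:
        a = X
        last = len(self.weights) - 1
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            z = a @ W + b
            a = z if i == last else _act(self.activation, z)
        return a[:, 0]

    # --- training ---------------------------------------------------------

    def _forward_train(self, X, dropout_rate, rng):
        acts, zs, masks = [X], [], []
        a = X
        last = len(self.weights) - 1
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            z = a @ W + b
            zs.append(z)
            if i == last:
                a = z
            else:
                a = _act(self.activation, z)
                if dropout_rate > 0:
                    mask = (rng.random(a.shape) >= dropout_rate) / (1.0 - dropout_rate)
                    a = a * mask
                    masks.append(mask)
                else:
                    masks.append(None)
            acts.append(a)
        return acts, zs, masks

    @staticmethod
    def _loss_and_residual_grad(pred, y, loss):
        r = pred - y
        if loss == "mse":
            return float(np.mean(r * r)), 2.0 * r / len(r)
        if loss == "huber":
            d = _HUBER_DELTA
            small = np.abs(r) <= d
            vals = np.where(small, 0.5 * r * r, d * (np.abs(r) - 0.5 * d))
            grad = np.where(small, r, d * np.sign(r)) / len(r)
            return float(np.mean(vals)), grad
        raise ValueError(f"unknown loss {loss!r}")

    def _backward(self, acts, zs, masks, dloss_dpred):
        grads_W = [None] * len(self.weights)
        grads_b = [None] * len(self.weights)
        delta = dloss_dpred[:, None]  # output layer is linear
        last = len(self.weights) - 1
        for i in range(last, -1, -1):
            grads_W[i] = acts[i].T @ delta
            grads_b[i] = delta.sum(axis=0)
            if i > 0:
                delta = delta @ self.weights[i].T
                if masks[i - 1] is not None:
                    delta = delta * masks[i - 1]
                delta = delta * _act_grad(self.activation, zs[i - 1], acts[i])
        return grads_W, grads_b

    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        *,
        X_val: np.ndarray,
        y_val: np.ndarray,
        loss: str = "huber",
        optimizer: str = "sgd_momentum",
        learning_rate: float = 5e-5,
        momentum: float = 0.9,
        batch_size: int = 32,
        max_epochs: int = 200,
        patience: int = 20,
        dropout_rate: float = 0.0,
        rng: np.random.Generator | None = None,
    ) -> dict:
        """Train in place; returns metadata (epochs run, best val loss)."""
        rng = rng or np.random.default_rng(0)
        n = len(X)
        vel_W = [np.zeros_like(W) for W in self.weights]
        vel_b = [np.zeros_like(b) for b in self.biases]
        if optimizer == "adam":
            m_W = [np.zeros_like(W) for W in self.weights]
            v_W = [np.zeros_like(W) for W in self.weights]
            m_b = [np.zeros_like(b) for b in self.biases]
            v_b = [np.zeros_like(b) for b in self.biases]
            b1, b2, eps, t_step = 0.9, 0.999, 1e-8, 0

        best_val = np.inf
        best_state = None
        stall = 0
        epochs_run = 0
        for epoch in range(max_epochs):
            order = rng.permutation(n)
            for start in range(0, n, batch_size):
                idx = order[start : start + batch_size]
                acts, zs, masks = self._forward_train(X[idx], dropout_rate, rng)
                batch_loss, dgrad = self._loss_and_residual_grad(acts[-1][:, 0], y[idx], loss)
                if not np.isfinite(batch_loss):
                    raise TrainingFailure(f"non-finite training loss at epoch {epoch}")
                gW, gb = self._backward(acts, zs, masks, dgrad)
                if optimizer == "sgd_momentum":
                    for i in range(len(self.weights)):
                        vel_W[i] = momentum * vel_W[i] - learning_rate * gW[i]
                        vel_b[i] = momentum * vel_b[i] - learning_rate * gb[i]
                        self.weights[i] += vel_W[i]
                        self.biases[i] += vel_b[i]
                elif optimizer == "adam":
                    t_step += 1
                    for i in range(len(self.weights)):
                        m_W[i] = b1 * m_W[i] + (1 - b1) * gW[i]
                        v_W[i] = b2 * v_W[i] + (1 - b2) * gW[i] ** 2
                        m_b[i] = b1 * m_b[i] + (1 - b1) * gb[i]
                        v_b[i] = b2 * v_b[i] + (1 - b2) * gb[i] ** 2
                        mc = 1 - b1**t_step
                        vc = 1 - b2**t_step
                        self.weights[i] -= learning_rate * (m_W[i] / mc) / (
                            np.sqrt(v_W[i] / vc) + eps
                        )
                        self.biases[i] -= learning_rate * (m_b[i] / mc) / (
                            np.sqrt(v_b[i] / vc) + eps
                        )
                else:
                    raise ValueError(f"unknown optimizer {optimizer!r}")

            epochs_run = epoch + 1
            val_loss, _ = self._loss_and_residual_grad(self.forward(X_val), y_val, loss)
            if not np.isfinite(val_loss):
                raise TrainingFailure(f"non-finite validation loss at epoch {epoch}")
            if val_loss < best_val - 1e-12:
                best_val = val_loss
                best_state = (
                    [W.copy() for W in self.weights],
                    [b.copy() for b in self.biases],
                )
                stall = 0
            else:
                stall += 1
                if stall >= patience:
                    break
        if best_state is not None:
            self.weights, self.biases = best_state
        return {"epochs_run": epochs_run, "best_val_loss": float(best_val)}
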