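"""Minimal fully-connected network with Adamax minibatch training.

Shared by the deep-autoencoder reconstruction backends and the routed
DNN classifiers.  Everything is plain numpy: the networks involved are
tiny (widest layer 15 neurons), so a framework would add nothing but a
heavyweight dependency, and pure-numpy arithmetic makes seeded fits
bit-reproducible across runs on the same platform.

Supported activations: relu, tanh, sigmoid, linear.  Losses: mean
squared error and binary cross-entropy, both averaged over every output
element (the Adamax defaults beta1=0.9, beta2=0.999, eps=1e-8 follow
the original adaptive-moment formulation).
"""

from __future__ import annotations

import numpy as np

_ACTIVATIONS = ("relu", "tanh", "sigmoid", "linear")


def _apply_activation(z: np.ndarray, name: str) -> np.ndarray:
    if name == "relu":
        return np.maximum(z, 0.0)
    if name == "tanh":
        return np.tanh(z)
    if name == "sigmoid":
        return 1.0 / (1.0 + np.exp(-z))
    if name == "linear":
        return z
    raise ValueError(f"unknown activation {name!r}")


def _activation_grad(a: np.ndarray, name: str) -> np.ndarray:
    # derivative expressed through the activation *output* a
    if name == "relu":
        return (a > 0).astype(a.dtype)
    if name == "tanh":
        return 1.0 - a * a
    if name == "sigmoid":
        return a * (1.0 - a)
    if name == "linear":
        return np.ones_like(a)
    raise ValueError(f"unknown activation {name!r}")


class MLP:
    """Feed-forward network: one activation per affine layer.

    Parameters
    ----------
    layer_widths:
        Node counts including input and output, e.g. ``[14, 10, 7, 4,
        7, 10, 14]`` gives six affine layers.
    activations:
        One name per affine layer (``len(layer_widths) - 1`` entries).
    seed:
        Seeds the weight initialisation (He-scaled normal for relu
        layers, Glorot-uniform otherwise).
    """

    def __init__(self, layer_widths, activations, seed=0):
        if len(activations) != len(layer_widths) - 1:
            raise ValueError("need one activation per affine layer")
        for a in activations:
            if a not in _ACTIVATIONS:
                raise ValueError(f"unknown activation {a!r}")
        if any(w <= 0 for w in layer_widths):
            raise ValueError("layer widths must be positive")
        self.layer_widths = [int(w) for w in layer_widths]
        self.activations = list(activations)
        rng = np.random.default_rng(seed)
        self.weights = []
        self.biases = []
        for fan_in, fan_out, act in zip(
            layer_widths[:-1], layer_widths[1:], activations
        ):
            if act == "relu":
                w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out))
            else:
                limit = np.sqrt(6.0 / (fan_in + fan_out))
                w = rng.uniform(-limit, limit, size=(fan_in, fan_out))
            self.weights.append(w)
            self.biases.append(np.zeros(fan_out))
        self.loss_history_: list[float] = []

    # ------------------------------------------------------------------
    def forward(self, X: np.ndarray) -> np.ndarray:
        h = np.asarray(X, dtype=float)
        for w, b, act in zip(self.weights, self.biases, self.activations):
            h = _apply_activation(h @ w + b, act)
        return h

    def _forward_cached(self, X):
        acts = [X]
        h = X
        for w, b, act in zip(self.weights, self.biases, self.activations):
            h = _apply_activation(h @ w + b, act)
            acts.append(h)
        return acts

    def loss(self, X: np.ndarray, Y: np.ndarray, kind: str = "mse") -> float:
        out = self.forward(X)
        Y = np.asarray(Y, dtype=float).reshape(out.shape)
        if kind == "mse":
            return float(np.mean((out - Y) ** 2))
        if kind == "cross_entropy":
            p = np.clip(out, 1e-12, 1.0 - 1e-12)
            return float(-np.mean(Y * np.log(p) + (1.0 - Y) * np.log(1.0 - p)))
        raise ValueError(f"unknown loss {kind!r}")

    # ------------------------------------------------------------------
    def fit(
        self,
        X: np.ndarray,
        Y: np.ndarray,
        *,
        learning_rate: float = 0.001,
        epochs: int = 200,
        batch_size: int = 32,
        loss: str = "mse",
        seed: int = 0,
    ) -> "MLP":
        """Minibatch Adamax on the configured loss.

        The minibatch order is reshuffled every epoch from ``seed``;
        ``loss_history_`` records the full-data loss after each epoch.
        Raises ``FloatingPointError`` if the loss goes non-finite.
        """
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        n = X.shape[0]
        rng = np.random.default_rng(seed)
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        m_w = [np.zeros_like(w) for w in self.weights]
        u_w = [np.zeros_like(w) for w in self.weights]
        m_b = [np.zeros_like(b) for b in self.biases]
        u_b = [np.zeros_like(b) for b in self.biases]
        t = 0
        self.loss_history_ = []
        n_layers = len(self.weights)
        for _ in range(epochs):
            perm = rng.permutation(n)
            for start in range(0, n, batch_size):
                idx = perm[start : start + batch_size]
                xb, yb = X[idx], Y[idx]
                acts = self._forward_cached(xb)
                out = acts[-1]
                if loss == "mse":
                    g = (2.0 / out.size) * (out - yb)
                    g = g * _activation_grad(out, self.activations[-1])
                elif loss == "cross_entropy":
                    if self.activations[-1] != "sigmoid":
                        raise ValueError("cross_entropy requires a sigmoid output")
                    # sigmoid + cross-entropy collapse to (p - y)/n on z
                    g = (out - yb) / out.size
                else:
                    raise ValueError(f"unknown loss {loss!r}")
                t += 1
                step = learning_rate / (1.0 - beta1**t)
                for i in range(n_layers - 1, -1, -1):
                    if i < n_layers - 1:
                        g = g * _activation_grad(acts[i + 1], self.activations[i])
                    gw = acts[i].T @ g
                    gb = g.sum(axis=0)
                    if i > 0:
                        g = g @ self.weights[i].T
                    m_w[i] = beta1 * m_w[i] + (1.0 - beta1) * gw
                    u_w[i] = np.maximum(beta2 * u_w[i], np.abs(gw))
                    self.weights[i] -= step * m_w[i] / (u_w[i] + eps)
                    m_b[i] = beta1 * m_b[i] + (1.0 - beta1) * gb
                    u_b[i] = np.maximum(beta2 * u_b[i], np.abs(gb))
                    self.biases[i] -= step * m_b[i] / (u_b[i] + eps)
            epoch_loss = self.loss(X, Y, kind=loss)
            if not np.isfinite(epoch_loss):
                raise FloatingPointError(
                    f"training loss became non-finite ({epoch_loss}) after "
                    f"{len(self.loss_history_) + 1} epochs; lower the learning rate"
                )
            self.loss_history_.append(epoch_loss)
        return self

    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "layer_widths": self.layer_widths,
            "activations": self.activations,
            "weights": [w.tolist() for w in self.weights],
            "biases": [b.tolist() for b in self.biases],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MLP":
        net = cls(d["layer_widths"], d["activations"], seed=0)
        net.weights = [np.asarray(w, dtype=float) for w in d["weights"]]
        net.biases = [np.asarray(b, dtype=float) for b in d["biases"]]
        return net
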