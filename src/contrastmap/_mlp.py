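"""Minimal feed-forward network toolkit used by the contrastive encoder.

Implements exactly the pieces the model needs — dense layers, batch
normalization, (leaky) ReLU, SGD with momentum and weight decay, and a
cosine learning-rate schedule — with explicit backward passes so the whole
training loop is plain numpy and deterministic under a seeded Generator.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Linear",
    "BatchNorm",
    "LeakyReLU",
    "ReLU",
    "Sequential",
    "SGD",
    "cosine_lr",
]


class Linear:
    """Dense layer y = x W + b with uniform(-1/sqrt(fan_in), ..) init."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        bound = 1.0 / np.sqrt(n_in)
        self.W = rng.uniform(-bound, bound, size=(n_in, n_out))
        self.b = rng.uniform(-bound, bound, size=n_out)
        self._x = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.W + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.dW = self._x.T @ dy
        self.db = dy.sum(axis=0)
        return dy @ self.W.T

    def params_grads(self):
        return [(self, "W", "dW"), (self, "b", "db")]


class BatchNorm:
    """Per-feature batch normalization with running inference statistics.

    Running variance is updated with the unbiased batch estimate; the
    normalization itself uses the biased one, matching common practice.
    """

    def __init__(self, n_features: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(n_features)
        self.beta = np.zeros(n_features)
        self.running_mean = np.zeros(n_features)
        self.running_var = np.ones(n_features)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mu = x.mean(axis=0)
            var = x.var(axis=0)
            n = x.shape[0]
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu
            unbiased = var * n / max(n - 1, 1)
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * unbiased
            self._inv_std = 1.0 / np.sqrt(var + self.eps)
            self._xhat = (x - mu) * self._inv_std
            return self.gamma * self._xhat + self.beta
        return self.gamma * (x - self.running_mean) / np.sqrt(self.running_var + self.eps) + self.beta

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._xhat, self._inv_std
        n = dy.shape[0]
        self.dgamma = (dy * xhat).sum(axis=0)
        self.dbeta = dy.sum(axis=0)
        dxhat = dy * self.gamma
        # standard batchnorm backward (mean and variance both depend on x)
        return (inv_std / n) * (
            n * dxhat - dxhat.sum(axis=0) - xhat * (dxhat * xhat).sum(axis=0)
        )

    def params_grads(self):
        return [(self, "gamma", "dgamma"), (self, "beta", "dbeta")]


class LeakyReLU:
    def __init__(self, slope: float = 0.01):
        self.slope = slope

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._mask = x >= 0
        return np.where(x >= 0, x, self.slope * x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, self.slope * dy)

    def params_grads(self):
        return []


class ReLU(LeakyReLU):
    def __init__(self):
        super().__init__(slope=0.0)


class Sequential:
    def __init__(self, layers):
        self.layers = list(layers)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def params_grads(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params_grads())
        return out


class SGD:
    """SGD with momentum; weight decay is added to the gradient (L2)."""

    def __init__(self, modules, momentum: float = 0.9, weight_decay: float = 5e-4):
        self.entries = []
        for module in modules:
            self.entries.extend(module.params_grads())
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.velocity = [np.zeros_like(getattr(obj, p)) for obj, p, _ in self.entries]

    def step(self, lr: float) -> None:
        for v, (obj, pname, gname) in zip(self.velocity, self.entries):
            param = getattr(obj, pname)
            grad = getattr(obj, gname) + self.weight_decay * param
            v *= self.momentum
            v += grad
            setattr(obj, pname, param - lr * v)


def cosine_lr(lr0: float, epoch: int, total_epochs: int) -> float:
    """Cosine decay from lr0 at epoch 0 toward 0 at the final epoch."""
    if total_epochs <= 1:
        return lr0
    return lr0 * 0.5 * (1.0 + np.cos(np.pi * epoch / total_epochs))
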