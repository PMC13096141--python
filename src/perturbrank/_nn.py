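"""Minimal feedforward neural-network building blocks (NumPy, CPU).

Dense layers, batch normalization, LeakyReLU/ReLU, dropout and an Adam
optimizer with manual backpropagation — everything the variational
autoencoder and the classifier ensemble need, deterministic under a seed.

Conventions: inputs are (batch, features) float64 arrays; each layer
implements forward(x, train) and backward(grad) and exposes (params, grads)
pairs for the optimizer.
"""

from __future__ import annotations

import numpy as np


class Dense:
    """Affine layer with He-style initialization."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.W + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.dW = self._x.T @ grad
        self.db = grad.sum(axis=0)
        return grad @ self.W.T

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


class BatchNorm:
    """Batch normalization over the batch axis with running statistics."""

    def __init__(self, n: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(n)
        self.beta = np.zeros(n)
        self.dgamma = np.zeros(n)
        self.dbeta = np.zeros(n)
        self.run_mean = np.zeros(n)
        self.run_var = np.ones(n)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            mu = x.mean(axis=0)
            var = x.var(axis=0)
            self.run_mean = self.momentum * self.run_mean + (1 - self.momentum) * mu
            self.run_var = self.momentum * self.run_var + (1 - self.momentum) * var
            xhat = (x - mu) / np.sqrt(var + self.eps)
            self._cache = (xhat, var)
            return self.gamma * xhat + self.beta
        xhat = (x - self.run_mean) / np.sqrt(self.run_var + self.eps)
        return self.gamma * xhat + self.beta

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, var = self._cache
        m = grad.shape[0]
        self.dgamma = (grad * xhat).sum(axis=0)
        self.dbeta = grad.sum(axis=0)
        dxhat = grad * self.gamma
        inv_std = 1.0 / np.sqrt(var + self.eps)
        return (inv_std / m) * (
            m * dxhat - dxhat.sum(axis=0) - xhat * (dxhat * xhat).sum(axis=0)
        )

    def params(self):
        return [(self.gamma, self.dgamma), (self.beta, self.dbeta)]


class Activation:
    """ReLU (slope=0) or LeakyReLU (slope>0)."""

    def __init__(self, slope: float = 0.0):
        self.slope = slope
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        mask = x > 0
        if train:
            self._mask = mask
        return np.where(mask, x, self.slope * x)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return np.where(self._mask, grad, self.slope * grad)

    def params(self):
        return []


class Dropout:
    def __init__(self, p: float, rng: np.random.Generator):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        self.p = p
        self.rng = rng
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if not train or self.p == 0.0:
            return x
        self._mask = self.rng.random(x.shape) >= self.p
        return x * self._mask / (1.0 - self.p)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self.p == 0.0:
            return grad
        return grad * self._mask / (1.0 - self.p)

    def params(self):
        return []


class Sequential:
    def __init__(self, layers: list):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params(self):
        return [p for layer in self.layers for p in layer.params()]


class Adam:
    """Adam with optional decoupled weight decay and L1/L2 loss penalties.

    L1/L2 penalty gradients are added to the raw gradients before the
    moment updates (penalties on all parameters of the tracked modules).
    """

    def __init__(self, modules: list, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8,
                 l1: float = 0.0, l2: float = 0.0, weight_decay: float = 0.0):
        self.modules = modules
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.l1, self.l2, self.weight_decay = l1, l2, weight_decay
        self.t = 0
        self._m = [np.zeros_like(p) for mod in modules for p, _ in mod.params()]
        self._v = [np.zeros_like(p) for mod in modules for p, _ in mod.params()]

    def step(self) -> None:
        self.t += 1
        i = 0
        for mod in self.modules:
            for p, g in mod.params():
                grad = g
                if self.l1:
                    grad = grad + self.l1 * np.sign(p)
                if self.l2:
                    grad = grad + 2.0 * self.l2 * p
                m = self._m[i] = self.beta1 * self._m[i] + (1 - self.beta1) * grad
                v = self._v[i] = self.beta2 * self._v[i] + (1 - self.beta2) * grad**2
                mhat = m / (1 - self.beta1**self.t)
                vhat = v / (1 - self.beta2**self.t)
                p -= self.lr * (mhat / (np.sqrt(vhat) + self.eps) + self.weight_decay * p)
                i += 1


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and its gradient w.r.t. logits."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = -np.log(p[np.arange(n), y] + 1e-12).mean()
    grad = p
    grad[np.arange(n), y] -= 1.0
    return loss, grad / n


def mlp(widths: list[int], rng: np.random.Generator, *, batch_norm: bool,
        slope: float = 0.0, dropout: float = 0.0) -> Sequential:
    """Stack of Dense(+BN)+activation(+dropout) blocks, no head activation.

    ``widths`` = [in, h1, ..., hk]: builds k hidden blocks; the caller adds
    its own output head on top of widths[-1].
    """
    layers: list = []
    for a, b in zip(widths[:-1], widths[1:]):
        layers.append(Dense(a, b, rng))
        if batch_norm:
            layers.append(BatchNorm(b))
        layers.append(Activation(slope))
        if dropout > 0:
            layers.append(Dropout(dropout, rng))
    return Sequential(layers)
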