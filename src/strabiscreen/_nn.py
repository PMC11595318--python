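"""Minimal fully-vectorized numpy MLP with the optimizer and loss families
used by the pupil regressors.

Kept deliberately small: dense layers with ReLU hidden activations and an
identity (linear) output, mini-batch training, and hand-written RMSprop /
Adam / Nadam update rules.  Everything is driven by a single
``numpy.random.Generator`` so training is bit-reproducible for a fixed seed
on a given platform.
"""

from __future__ import annotations

import numpy as np

OPTIMIZERS = ("RMSprop", "Adam", "Nadam")
LOSSES = ("MAE", "MSE", "LogCosh", "Huber", "MAPE", "CosineSimilarity")

_EPS = 1e-8


def loss_and_grad(name: str, y: np.ndarray, t: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean loss over a batch and its gradient w.r.t. predictions ``y``.

    ``y`` and ``t`` are (batch, 2) arrays.  Conventions follow the common
    deep-learning definitions: per-element means for MAE/MSE/LogCosh/Huber/
    MAPE (MAPE in percent), and negative mean cosine similarity between the
    prediction and target vectors for CosineSimilarity.
    """
    n = y.size
    d = y - t
    if name == "MSE":
        return float(np.mean(d * d)), 2.0 * d / n
    if name == "MAE":
        return float(np.mean(np.abs(d))), np.sign(d) / n
    if name == "LogCosh":
        # numerically stable log(cosh(x)) = |x| + log1p(exp(-2|x|)) - log 2
        a = np.abs(d)
        val = float(np.mean(a + np.log1p(np.exp(-2.0 * a)) - np.log(2.0)))
        return val, np.tanh(d) / n
    if name == "Huber":
        delta = 1.0
        a = np.abs(d)
        quad = np.minimum(a, delta)
        val = float(np.mean(0.5 * quad**2 + delta * (a - quad)))
        grad = np.where(a <= delta, d, delta * np.sign(d)) / n
        return val, grad
    if name == "MAPE":
        denom = np.maximum(np.abs(t), _EPS)
        val = float(100.0 * np.mean(np.abs(d) / denom))
        return val, 100.0 * np.sign(d) / (denom * n)
    if name == "CosineSimilarity":
        ny = np.linalg.norm(y, axis=1, keepdims=True)
        nt = np.linalg.norm(t, axis=1, keepdims=True)
        ny = np.maximum(ny, _EPS)
        nt = np.maximum(nt, _EPS)
        cos = np.sum(y * t, axis=1, keepdims=True) / (ny * nt)
        val = float(-np.mean(cos))
        b = y.shape[0]
        grad = -(t / (ny * nt) - cos * y / (ny * ny)) / b
        return val, grad
    raise ValueError(f"unknown loss {name!r}; valid: {LOSSES}")


class _Optimizer:
    def __init__(self, params: list[np.ndarray], lr: float):
        self.params = params
        self.lr = lr
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        raise NotImplementedError


class RMSprop(_Optimizer):
    def __init__(self, params, lr, rho: float = 0.9):
        super().__init__(params, lr)
        self.rho = rho
        self.v = [np.zeros_like(p) for p in params]

    def step(self, grads):
        for p, g, v in zip(self.params, grads, self.v):
            v *= self.rho
            v += (1.0 - self.rho) * g * g
            p -= self.lr * g / (np.sqrt(v) + _EPS)


class Adam(_Optimizer):
    def __init__(self, params, lr, beta1: float = 0.9, beta2: float = 0.999):
        super().__init__(params, lr)
        self.b1, self.b2 = beta1, beta2
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]

    def step(self, grads):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + _EPS)


class Nadam(Adam):
    """Adam with Nesterov momentum applied to the first-moment estimate."""

    def step(self, grads):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b1t_next = 1.0 - self.b1 ** (self.t + 1)
        b2t = 1.0 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            m_hat = self.b1 * m / b1t_next + (1.0 - self.b1) * g / b1t
            p -= self.lr * m_hat / (np.sqrt(v / b2t) + _EPS)


def make_optimizer(name: str, params: list[np.ndarray], lr: float) -> _Optimizer:
    if name == "RMSprop":
        return RMSprop(params, lr)
    if name == "Adam":
        return Adam(params, lr)
    if name == "Nadam":
        return Nadam(params, lr)
    raise ValueError(f"unknown optimizer {name!r}; valid: {OPTIMIZERS}")


class MLP:
    """Dense ReLU network with identity output activation."""

    def __init__(self, layer_sizes: list[int], rng: np.random.Generator):
        self.sizes = list(layer_sizes)
        self.W: list[np.ndarray] = []
        self.b: list[np.ndarray] = []
        for n_in, n_out in zip(layer_sizes[:-1], layer_sizes[1:]):
            # He initialization for the ReLU stack
            scale = np.sqrt(2.0 / n_in)
            self.W.append(rng.normal(0.0, scale, (n_in, n_out)))
            self.b.append(np.zeros(n_out))

    @property
    def params(self) -> list[np.ndarray]:
        return [*self.W, *self.b]

    def forward(self, X: np.ndarray, cache: list | None = None) -> np.ndarray:
        a = X
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            z = a @ W + b
            if i < len(self.W) - 1:
                if cache is not None:
                    cache.append((a, z))
                a = np.maximum(z, 0.0)
            else:
                if cache is not None:
                    cache.append((a, z))
                a = z  # linear output head
        return a

    def backward(self, cache: list, grad_out: np.ndarray) -> list[np.ndarray]:
        """Gradients in the same order as ``params``."""
        gW = [None] * len(self.W)
        gb = [None] * len(self.b)
        delta = grad_out
        for i in reversed(range(len(self.W))):
            a_in, z = cache[i]
            if i < len(self.W) - 1:
                delta = delta * (z > 0)
            gW[i] = a_in.T @ delta
            gb[i] = delta.sum(axis=0)
            if i > 0:
                delta = delta @ self.W[i].T
        return [*gW, *gb]

    def state_dict(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {"sizes": np.asarray(self.sizes)}
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            out[f"W{i}"] = W
            out[f"b{i}"] = b
        return out

    @classmethod
    def from_state_dict(cls, state: dict) -> "MLP":
        sizes = [int(s) for s in np.asarray(state["sizes"])]
        net = cls.__new__(cls)
        net.sizes = sizes
        net.W = [np.asarray(state[f"W{i}"], dtype=np.float64) for i in range(len(sizes) - 1)]
        net.b = [np.asarray(state[f"b{i}"], dtype=np.float64) for i in range(len(sizes) - 1)]
        return net
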