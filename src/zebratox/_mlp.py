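"""Minimal dense-network machinery: layers, backprop, optimizers.

Implements exactly the ingredients the generator/discriminator networks
need — dense layers with Gaussian weight init, batch normalization between
layers, swish activations, mean-squared-error loss, and SGD/Adam updates —
in plain numpy with hand-written backward passes. Everything is
deterministic given the numpy Generator used for initialization and
batching.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

__all__ = ["Dense", "BatchNorm", "Swish", "Sequential", "SGD", "Adam", "mse_loss"]


class Param:
    """A trainable array with its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


class Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        # Gaussian kernel initializer, scaled by fan-in to keep activations O(1)
        w = rng.standard_normal((n_in, n_out)) / np.sqrt(n_in)
        self.W = Param(w)
        self.b = Param(np.zeros(n_out))
        self._x: np.ndarray | None = None

    @property
    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.W.grad += self._x.T @ dout
        self.b.grad += dout.sum(axis=0)
        return dout @ self.W.value.T


class BatchNorm:
    def __init__(self, n: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Param(np.ones(n))
        self.beta = Param(np.zeros(n))
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(n)
        self.running_var = np.ones(n)
        self._cache = None

    @property
    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        if train:
            self._cache = (xhat, inv, x.shape[0])
        return self.gamma.value * xhat + self.beta.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv, m = self._cache
        self.gamma.grad += (dout * xhat).sum(axis=0)
        self.beta.grad += dout.sum(axis=0)
        dxhat = dout * self.gamma.value
        # standard batch-norm backward (training statistics)
        return inv / m * (m * dxhat - dxhat.sum(axis=0) - xhat * (dxhat * xhat).sum(axis=0))


class Swish:
    """x * sigmoid(x); used on hidden AND output layers of the generators."""

    params: list = []

    def __init__(self):
        self._cache = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        s = expit(x)
        if train:
            self._cache = (x, s)
        return x * s

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x, s = self._cache
        return dout * (s + x * s * (1.0 - s))


class Identity:
    params: list = []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout


class Sequential:
    def __init__(self, layers: list):
        self.layers = layers

    @property
    def params(self):
        return [p for layer in self.layers for p in layer.params]

    def n_parameters(self) -> int:
        return sum(p.value.size for p in self.params)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def state_arrays(self) -> dict[str, np.ndarray]:
        """All trainable values plus batch-norm running statistics."""
        out = {}
        for i, layer in enumerate(self.layers):
            for j, p in enumerate(layer.params):
                out[f"layer{i}_param{j}"] = p.value
            if isinstance(layer, BatchNorm):
                out[f"layer{i}_running_mean"] = layer.running_mean
                out[f"layer{i}_running_var"] = layer.running_var
        return out

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            for j, p in enumerate(layer.params):
                p.value[...] = state[f"layer{i}_param{j}"]
            if isinstance(layer, BatchNorm):
                layer.running_mean[...] = state[f"layer{i}_running_mean"]
                layer.running_var[...] = state[f"layer{i}_running_var"]


def make_mlp(
    n_in: int,
    hidden: list[int],
    n_out: int,
    rng: np.random.Generator,
    batchnorm: bool = True,
    output_activation: str = "swish",
) -> Sequential:
    """Dense -> [BatchNorm] -> Swish stack with a swish or linear output."""
    layers: list = []
    prev = n_in
    for width in hidden:
        layers.append(Dense(prev, width, rng))
        if batchnorm:
            layers.append(BatchNorm(width))
        layers.append(Swish())
        prev = width
    layers.append(Dense(prev, n_out, rng))
    layers.append(Swish() if output_activation == "swish" else Identity())
    return Sequential(layers)


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error and its gradient w.r.t. pred."""
    diff = pred - target
    loss = float(np.mean(diff**2))
    return loss, 2.0 * diff / diff.size


class SGD:
    """Stochastic gradient descent, optional classical momentum."""

    def __init__(self, params, lr: float, momentum: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self._vel = [np.zeros_like(p.value) for p in self.params]

    def step(self) -> None:
        for p, v in zip(self.params, self._vel):
            if self.momentum:
                v *= self.momentum
                v -= self.lr * p.grad
                p.value += v
            else:
                p.value -= self.lr * p.grad


class Adam:
    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self._m = [np.zeros_like(p.value) for p in self.params]
        self._v = [np.zeros_like(p.value) for p in self.params]
        self._t = 0

    def step(self) -> None:
        self._t += 1
        b1t = 1.0 - self.beta1**self._t
        b2t = 1.0 - self.beta2**self._t
        for p, m, v in zip(self.params, self._m, self._v):
            m *= self.beta1
            m += (1 - self.beta1) * p.grad
            v *= self.beta2
            v += (1 - self.beta2) * p.grad**2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
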