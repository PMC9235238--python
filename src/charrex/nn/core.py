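"""Minimal parameter/module machinery for the NumPy model.

Every layer implements ``forward`` (caching what backward needs) and
``backward`` (returning the gradient w.r.t. its input while accumulating
parameter gradients in place).  No autograd: each backward pass is
written against the layer's own equations, which is what the
finite-difference gradient checks exercise.
"""

from __future__ import annotations

import numpy as np


class Parameter:
    """A trainable tensor with an accumulated gradient."""

    __slots__ = ("value", "grad", "name", "frozen_rows")

    def __init__(self, value: np.ndarray, name: str = "", frozen_rows: list[int] | None = None):
        self.value = np.asarray(value)
        self.grad = np.zeros_like(self.value)
        self.name = name
        # rows pinned at their initial value (e.g. PAD embedding rows)
        self.frozen_rows = frozen_rows or []

    @property
    def shape(self):
        return self.value.shape

    def zero_grad(self) -> None:
        self.grad[...] = 0.0

    def apply_freeze(self) -> None:
        for r in self.frozen_rows:
            self.grad[r] = 0.0


class Module:
    """Base class providing a recursive parameter walk."""

    def parameters(self) -> list[Parameter]:
        out: list[Parameter] = []
        for attr in vars(self).values():
            out.extend(_collect(attr))
        return out

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()


def _collect(obj) -> list[Parameter]:
    if isinstance(obj, Parameter):
        return [obj]
    if isinstance(obj, Module):
        return obj.parameters()
    if isinstance(obj, (list, tuple)):
        out: list[Parameter] = []
        for item in obj:
            out.extend(_collect(item))
        return out
    return []


def uniform_init(rng: np.random.Generator, shape, scale: float = 0.25, dtype=np.float32):
    return rng.uniform(-scale, scale, size=shape).astype(dtype)


def glorot_init(rng: np.random.Generator, fan_in: int, fan_out: int, shape=None, dtype=np.float32):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    shape = shape if shape is not None else (fan_in, fan_out)
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


class Dropout:
    """Inverted dropout; identity when rate is 0 or in eval mode."""

    def __init__(self, rate: float):
        self.rate = rate
        self._mask = None

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator | None) -> np.ndarray:
        if not train or self.rate <= 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dout
        return dout * self._mask


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, dtype=np.float32):
        self.W = Parameter(glorot_init(rng, d_in, d_out, dtype=dtype), "linear.W")
        self.b = Parameter(np.zeros(d_out, dtype=dtype), "linear.b")
        self._x = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.W.grad += self._x.T @ dout
        self.b.grad += dout.sum(axis=0)
        return dout @ self.W.value.T
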