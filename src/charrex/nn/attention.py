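"""Character-level attention pooling, branch fusion and the softmax head.

Each branch (residual and recurrent) owns an independent scoring vector
w and bias b.  Per-position scores u_i = tanh(w . H_i + b) are
softmax-normalized over the unpadded prefix (masked positions get
exactly zero weight) and the branch summary is S = sum_i a_i H_i.  The
two summaries are fused by concatenation — the branch dimensions differ
(e.g. 384 vs 1024 at full defaults), which rules out summation — and a
fully connected layer with softmax produces the distribution over the r
relation categories (UNKNOWN included).
"""

from __future__ import annotations

import numpy as np

from .core import Dropout, Linear, Module, Parameter, uniform_init


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


class AttentionParams(Module):
    def __init__(self, d: int, rng: np.random.Generator, dtype=np.float32):
        self.w = Parameter(uniform_init(rng, (d,), scale=0.1, dtype=dtype), "att.w")
        self.b = Parameter(np.zeros((), dtype=dtype), "att.b")


class AttentionPool(Module):
    """Masked softmax pooling with learned scalar scores."""

    def __init__(self, d: int, rng: np.random.Generator, dtype=np.float32):
        self.params = AttentionParams(d, rng, dtype)
        self._cache = None

    def forward(self, H: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """H: (B, L, d); mask: (B, L) -> (weights (B, L), pooled (B, d))."""
        if not mask.any(axis=1).all():
            raise ValueError("attention over an empty (all-masked) sequence")
        u = np.tanh(H @ self.params.w.value + self.params.b.value)  # (B, L)
        u_masked = np.where(mask > 0, u, -np.inf)
        a = softmax(u_masked, axis=1)
        a = np.where(mask > 0, a, 0.0).astype(H.dtype)
        S = np.einsum("bl,bld->bd", a, H)
        self._cache = (H, mask, u, a)
        return a, S

    def backward(self, dS: np.ndarray, da_extra: np.ndarray | None = None) -> np.ndarray:
        H, mask, u, a = self._cache
        da = np.einsum("bd,bld->bl", dS, H)
        if da_extra is not None:
            da = da + da_extra
        dH = a[:, :, None] * dS[:, None, :]
        # softmax jacobian: du = a * (da - sum_j a_j da_j)
        du = a * (da - (a * da).sum(axis=1, keepdims=True))
        du = du * (1.0 - u * u) * (mask > 0)  # u is the tanh output
        self.params.w.grad += np.einsum("bl,bld->d", du, H)
        self.params.b.grad += du.sum()
        dH += du[:, :, None] * self.params.w.value[None, None, :]
        return dH


def fuse(S_c: np.ndarray, S_G: np.ndarray) -> np.ndarray:
    """Concatenate the residual-branch and recurrent-branch summaries."""
    return np.concatenate([S_c, S_G], axis=-1)


class ClassifierHead(Module):
    """Dropout + fully connected layer + softmax over r categories."""

    def __init__(self, d_in: int, r: int, rng: np.random.Generator,
                 dropout: float = 0.5, dtype=np.float32):
        self.r = r
        self.fc = Linear(d_in, r, rng, dtype)
        self.dropout = Dropout(dropout)

    def forward(self, S: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        """Returns class probabilities (B, r)."""
        self._logits = self.fc.forward(self.dropout.forward(S, train, rng))
        return softmax(self._logits, axis=-1)

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        return self.dropout.backward(self.fc.backward(dlogits))


def classify(S: np.ndarray, head: ClassifierHead) -> np.ndarray:
    """Probability vector(s) over the head's r labels."""
    squeeze = S.ndim == 1
    probs = head.forward(S[None, :] if squeeze else S, train=False)
    return probs[0] if squeeze else probs
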