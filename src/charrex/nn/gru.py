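"""Bidirectional gated recurrent encoder with mask-aware state stitching.

The cell follows the standard GRU update

    z_t = sigma(W_z [h_{t-1}, X_t] + b_z)
    r_t = sigma(W_r [h_{t-1}, X_t] + b_r)
    h~_t = tanh(W_h [r_t (*) h_{t-1}, X_t] + b_h)
    h_t = (1 - z_t) (*) h_{t-1} + z_t (*) h~_t

with (*) the elementwise (Hadamard) product.  The backward direction
processes only the unpadded prefix of each sequence (the prefix is
reversed in place, run through a forward recurrence, and un-reversed),
so padding never leaks into the last real position's backward state.
Per-position output is the concatenation [h_fwd_t, h_bwd_t]; positions
beyond the true length are zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Dropout, Module, Parameter, glorot_init, sigmoid


@dataclass(frozen=True)
class BiGRUConfig:
    hidden: int = 512
    layers: int = 3
    dropout: float = 0.5  # between stacked layers

    def __post_init__(self) -> None:
        if self.hidden <= 0 or self.layers < 1:
            raise ValueError("hidden size must be positive and layers >= 1")


class GRUCellParams(Module):
    """Gate weights acting on the concatenation [h_{t-1}, X_t]."""

    def __init__(self, d_in: int, hidden: int, rng: np.random.Generator, dtype=np.float32):
        self.d_in = d_in
        self.hidden = hidden
        d = d_in + hidden
        self.W_z = Parameter(glorot_init(rng, d, hidden, dtype=dtype), "gru.W_z")
        self.W_r = Parameter(glorot_init(rng, d, hidden, dtype=dtype), "gru.W_r")
        self.W_h = Parameter(glorot_init(rng, d, hidden, dtype=dtype), "gru.W_h")
        self.b_z = Parameter(np.zeros(hidden, dtype=dtype), "gru.b_z")
        self.b_r = Parameter(np.zeros(hidden, dtype=dtype), "gru.b_r")
        self.b_h = Parameter(np.zeros(hidden, dtype=dtype), "gru.b_h")


def _cell_forward(x_t: np.ndarray, h_prev: np.ndarray, p: GRUCellParams):
    inp = np.concatenate([h_prev, x_t], axis=-1)
    z = sigmoid(inp @ p.W_z.value + p.b_z.value)
    r = sigmoid(inp @ p.W_r.value + p.b_r.value)
    inp_h = np.concatenate([r * h_prev, x_t], axis=-1)
    hc = np.tanh(inp_h @ p.W_h.value + p.b_h.value)
    h_t = (1.0 - z) * h_prev + z * hc
    cache = (x_t, h_prev, z, r, hc, inp, inp_h)
    return h_t, cache


def _cell_backward(dh: np.ndarray, cache, p: GRUCellParams):
    x_t, h_prev, z, r, hc, inp, inp_h = cache
    H = p.hidden
    dz = dh * (hc - h_prev)
    dhc = dh * z
    dh_prev = dh * (1.0 - z)
    da_h = dhc * (1.0 - hc * hc)
    p.W_h.grad += inp_h.T @ da_h
    p.b_h.grad += da_h.sum(axis=0)
    dinp_h = da_h @ p.W_h.value.T
    drh, dx = dinp_h[:, :H], dinp_h[:, H:].copy()
    dr = drh * h_prev
    dh_prev += drh * r
    da_z = dz * z * (1.0 - z)
    da_r = dr * r * (1.0 - r)
    p.W_z.grad += inp.T @ da_z
    p.b_z.grad += da_z.sum(axis=0)
    p.W_r.grad += inp.T @ da_r
    p.b_r.grad += da_r.sum(axis=0)
    dinp = da_z @ p.W_z.value.T + da_r @ p.W_r.value.T
    dh_prev += dinp[:, :H]
    dx += dinp[:, H:]
    return dx, dh_prev


def gru_step(x_t: np.ndarray, h_prev: np.ndarray, params: GRUCellParams) -> np.ndarray:
    """Single GRU update; accepts (d,) vectors or (B, d) batches."""
    squeeze = x_t.ndim == 1
    if squeeze:
        x_t, h_prev = x_t[None, :], h_prev[None, :]
    h_t, _ = _cell_forward(x_t, h_prev, params)
    return h_t[0] if squeeze else h_t


class MaskedGRU(Module):
    """Unidirectional recurrence over a padded batch.

    At masked steps the carried state is held and the output is zero,
    so appending PAD positions never changes states over the true
    prefix.
    """

    def __init__(self, d_in: int, hidden: int, rng: np.random.Generator, dtype=np.float32):
        self.cell = GRUCellParams(d_in, hidden, rng, dtype)
        self._caches = None
        self._mask = None

    def forward(self, X: np.ndarray, mask: np.ndarray) -> np.ndarray:
        """X: (B, L, d_in); mask: (B, L) in {0,1} -> (B, L, hidden)."""
        B, L, _ = X.shape
        H = self.cell.hidden
        h = np.zeros((B, H), dtype=X.dtype)
        out = np.zeros((B, L, H), dtype=X.dtype)
        caches = []
        for t in range(L):
            m = mask[:, t : t + 1].astype(X.dtype)
            h_new, cache = _cell_forward(X[:, t, :], h, self.cell)
            h = m * h_new + (1.0 - m) * h
            out[:, t, :] = m * h
            caches.append((cache, m))
        self._caches, self._mask = caches, mask
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, L, H = dout.shape
        dX = np.zeros((B, L, self.cell.d_in), dtype=dout.dtype)
        dcarry = np.zeros((B, H), dtype=dout.dtype)
        for t in range(L - 1, -1, -1):
            cache, m = self._caches[t]
            g_state = dcarry + m * dout[:, t, :]
            dx, dh_prev = _cell_backward(m * g_state, cache, self.cell)
            dX[:, t, :] = dx
            dcarry = (1.0 - m) * g_state + dh_prev
        return dX


def _reverse_index(lengths: np.ndarray, L: int) -> np.ndarray:
    """Per-row permutation reversing the valid prefix; an involution."""
    t = np.arange(L)[None, :]
    ln = lengths[:, None]
    return np.where(t < ln, ln - 1 - t, t)


def _gather_time(X: np.ndarray, idx: np.ndarray) -> np.ndarray:
    return np.take_along_axis(X, idx[:, :, None], axis=1)


class BiGRU(Module):
    """Stacked bidirectional GRU; per-position output is the stitched
    [forward, backward] state pair (dimension 2 * hidden)."""

    def __init__(self, d_in: int, config: BiGRUConfig, rng: np.random.Generator, dtype=np.float32):
        self.config = config
        self.layers_fwd: list[MaskedGRU] = []
        self.layers_bwd: list[MaskedGRU] = []
        d = d_in
        for _ in range(config.layers):
            self.layers_fwd.append(MaskedGRU(d, config.hidden, rng, dtype))
            self.layers_bwd.append(MaskedGRU(d, config.hidden, rng, dtype))
            d = 2 * config.hidden
        self.dropouts = [Dropout(config.dropout) for _ in range(config.layers - 1)]
        self._idx = None

    @property
    def d_out(self) -> int:
        return 2 * self.config.hidden

    def forward(self, X: np.ndarray, lengths: np.ndarray, mask: np.ndarray,
                train: bool = False, rng: np.random.Generator | None = None) -> np.ndarray:
        B, L, _ = X.shape
        self._idx = _reverse_index(lengths, L)
        h = X
        for k in range(self.config.layers):
            if k > 0:
                h = self.dropouts[k - 1].forward(h, train, rng)
            fwd = self.layers_fwd[k].forward(h, mask)
            bwd = _gather_time(self.layers_bwd[k].forward(_gather_time(h, self._idx), mask),
                               self._idx)
            h = np.concatenate([fwd, bwd], axis=2)
        return h

    def backward(self, dout: np.ndarray) -> np.ndarray:
        H = self.config.hidden
        d = dout
        for k in range(self.config.layers - 1, -1, -1):
            dfwd = self.layers_fwd[k].backward(np.ascontiguousarray(d[:, :, :H]))
            dbwd_rev = self.layers_bwd[k].backward(_gather_time(np.ascontiguousarray(d[:, :, H:]),
                                                                self._idx))
            d = dfwd + _gather_time(dbwd_rev, self._idx)
            if k > 0:
                d = self.dropouts[k - 1].backward(d)
        return d
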