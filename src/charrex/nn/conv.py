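"""Residual convolutional encoder over the embedded character sequence.

A multi-window stem convolution (one branch per window size,
concatenated on the channel axis) is followed by a stack of residual
blocks.  Each block holds two window-3 convolutions with ReLU after
each, and combines through an identity shortcut:

    c_l     = ReLU(w_1 * c + b_1)
    c_{l+1} = ReLU(w_2 * c_l + b_2)
    c_hat   = ReLU(c_{l+1} + c)

All convolutions use same-length zero padding so the output keeps
per-position resolution for attention pooling.  Total convolution-layer
count ("depth") is 1 stem + 2 per block; the depth variants
{5, 9, 11, 13} correspond to {2, 4, 5, 6} blocks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .core import Module, Parameter, glorot_init


@dataclass(frozen=True)
class ConvSpec:
    """Stem convolution geometry: one branch per odd window size, each
    with n_filters output channels."""

    window_sizes: tuple[int, ...] = (3, 5, 7)
    n_filters: int = 128

    def __post_init__(self) -> None:
        if self.n_filters <= 0:
            raise ValueError("n_filters must be positive")
        for h in self.window_sizes:
            if h <= 0 or h % 2 == 0:
                raise ValueError(f"window size {h} must be odd and positive")

    @property
    def d_c(self) -> int:
        """Channel count of the residual stack (= stem output channels)."""
        return self.n_filters * len(self.window_sizes)


@dataclass(frozen=True)
class ResNetConfig:
    """Depth = total convolution count: 1 stem + 2 per residual block."""

    depth: int = 11
    use_shortcuts: bool = True  # ablation switch

    def __post_init__(self) -> None:
        if self.depth < 3 or self.depth % 2 == 0:
            raise ValueError("depth must be odd and >= 3 (1 stem + 2 per block)")

    @property
    def n_blocks(self) -> int:
        return (self.depth - 1) // 2


class Conv1dSame(Module):
    """1-D convolution with same-length zero padding, as a matmul over
    unfolded windows."""

    def __init__(self, h: int, c_in: int, c_out: int, rng: np.random.Generator, dtype=np.float32):
        if h % 2 == 0:
            raise ValueError("window must be odd for same-length padding")
        self.h = h
        self.c_in = c_in
        self.c_out = c_out
        self.W = Parameter(glorot_init(rng, h * c_in, c_out, dtype=dtype), f"conv{h}.W")
        self.b = Parameter(np.zeros(c_out, dtype=dtype), f"conv{h}.b")
        self._cols = None
        self._in_shape = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        """x: (B, L, c_in) -> (B, L, c_out), linear part only."""
        B, L, C = x.shape
        p = self.h // 2
        xp = np.zeros((B, L + 2 * p, C), dtype=x.dtype)
        xp[:, p : p + L] = x
        # (B, L, h, C): window k covers input positions t-p .. t+p
        cols = sliding_window_view(xp, self.h, axis=1).transpose(0, 1, 3, 2)
        cols = np.ascontiguousarray(cols).reshape(B * L, self.h * C)
        self._cols, self._in_shape = cols, (B, L, C)
        out = cols @ self.W.value + self.b.value
        return out.reshape(B, L, self.c_out)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, L, C = self._in_shape
        d2 = dout.reshape(B * L, self.c_out)
        self.W.grad += self._cols.T @ d2
        self.b.grad += d2.sum(axis=0)
        dcols = (d2 @ self.W.value.T).reshape(B, L, self.h, C)
        p = self.h // 2
        dxp = np.zeros((B, L + 2 * p, C), dtype=dout.dtype)
        for k in range(self.h):
            dxp[:, k : k + L] += dcols[:, :, k, :]
        return dxp[:, p : p + L]


class _ReLU:
    def __init__(self):
        self._pos = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._pos = x > 0
        return np.maximum(x, 0.0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._pos


class ResidualBlock(Module):
    """Two window-h convolutions with ReLUs and an identity shortcut."""

    def __init__(self, channels: int, rng: np.random.Generator, h: int = 3,
                 use_shortcut: bool = True, dtype=np.float32):
        self.conv1 = Conv1dSame(h, channels, channels, rng, dtype)
        self.conv2 = Conv1dSame(h, channels, channels, rng, dtype)
        self.use_shortcut = use_shortcut
        self._f1, self._f2, self._g = _ReLU(), _ReLU(), _ReLU()

    def forward(self, c: np.ndarray) -> np.ndarray:
        c_l = self._f1.forward(self.conv1.forward(c))
        c_l1 = self._f2.forward(self.conv2.forward(c_l))
        pre = c_l1 + c if self.use_shortcut else c_l1
        return self._g.forward(pre)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dpre = self._g.backward(dout)
        dc = self.conv1.backward(self._f1.backward(self.conv2.backward(self._f2.backward(dpre))))
        if self.use_shortcut:
            dc = dc + dpre
        return dc


class ResNetEncoder(Module):
    """Stem (multi-window, channel-concatenated) + residual stack.

    Output: (B, L, d_c) per-position features, d_c = n_windows * n_filters.
    """

    def __init__(self, d_v: int, spec: ConvSpec, config: ResNetConfig,
                 rng: np.random.Generator, dtype=np.float32):
        self.spec = spec
        self.config = config
        self.stem = [Conv1dSame(h, d_v, spec.n_filters, rng, dtype) for h in spec.window_sizes]
        self._stem_relu = _ReLU()
        self.blocks = [
            ResidualBlock(spec.d_c, rng, h=3, use_shortcut=config.use_shortcuts, dtype=dtype)
            for _ in range(config.n_blocks)
        ]

    def conv_layer_count(self) -> int:
        """Structural audit: number of convolution layers in the stack.

        The multi-window stem is one layer (parallel branches of the
        same level); each residual block contributes two.
        """
        return 1 + 2 * len(self.blocks)

    def forward(self, x: np.ndarray) -> np.ndarray:
        feats = np.concatenate([conv.forward(x) for conv in self.stem], axis=2)
        h = self._stem_relu.forward(feats)
        for block in self.blocks:
            h = block.forward(h)
        return h

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for block in reversed(self.blocks):
            dout = block.backward(dout)
        dfeats = self._stem_relu.backward(dout)
        dx = None
        off = 0
        for conv in self.stem:
            part = dfeats[:, :, off : off + self.spec.n_filters]
            g = conv.backward(np.ascontiguousarray(part))
            dx = g if dx is None else dx + g
            off += self.spec.n_filters
        return dx
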