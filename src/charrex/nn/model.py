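"""The full hybrid relation-extraction model.

Pipeline per instance: character + two position embedding lookups
(d_v = d_w + 2 d_p per character) feed two parallel encoders — the
residual convolutional stack and the stacked bidirectional GRU — each
pooled by its own attention; the pooled summaries are concatenated and
classified by a softmax head over the r relation categories.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..encoding import EmbeddingSpec, EncodedBatch, PAD_ID
from .attention import AttentionPool, ClassifierHead, fuse
from .conv import ConvSpec, ResNetConfig, ResNetEncoder
from .core import Module, Parameter, uniform_init
from .gru import BiGRU, BiGRUConfig


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters; defaults mirror the published
    configuration (character dim 300, position dim 25, windows 3/5/7
    with 128 filters, depth-11 residual stack, 3 BiGRU layers of 512
    hidden units, dropout 0.5)."""

    embedding: EmbeddingSpec = field(default_factory=EmbeddingSpec)
    conv: ConvSpec = field(default_factory=ConvSpec)
    resnet: ResNetConfig = field(default_factory=ResNetConfig)
    gru: BiGRUConfig = field(default_factory=BiGRUConfig)
    n_classes: int = 12
    dropout: float = 0.5
    dtype: str = "float32"

    @property
    def fused_dim(self) -> int:
        return self.conv.d_c + 2 * self.gru.hidden

    @staticmethod
    def reduced(n_classes: int, L_max: int = 64, hidden: int = 64,
                n_filters: int = 64, depth: int = 5, d_w: int = 32, d_p: int = 8,
                p_max: int = 64) -> "ModelConfig":
        """Desk-scale variant for CPU experiments and tests."""
        return ModelConfig(
            embedding=EmbeddingSpec(d_w=d_w, d_p=d_p, p_max=p_max, L_max=L_max),
            conv=ConvSpec(window_sizes=(3,), n_filters=n_filters),
            resnet=ResNetConfig(depth=depth),
            gru=BiGRUConfig(hidden=hidden, layers=1, dropout=0.0),
            n_classes=n_classes,
        )

    def architecture_hash(self) -> str:
        import hashlib

        return hashlib.sha1(repr(self).encode()).hexdigest()[:12]


class RelationModel(Module):
    """End-to-end model with manual forward/backward passes."""

    def __init__(self, config: ModelConfig, vocab_size: int, rng: np.random.Generator,
                 char_table: np.ndarray | None = None):
        self.config = config
        dtype = np.dtype(config.dtype).type
        emb = config.embedding
        if char_table is not None:
            if char_table.shape != (vocab_size, emb.d_w):
                raise ValueError(
                    f"pretrained table shape {char_table.shape} != ({vocab_size}, {emb.d_w})"
                )
            char0 = char_table.astype(dtype)
        else:
            char0 = uniform_init(rng, (vocab_size, emb.d_w), dtype=dtype)
        char0[PAD_ID] = 0.0
        self.char_emb = Parameter(char0, "emb.char", frozen_rows=[PAD_ID])
        self.pos1_emb = Parameter(
            uniform_init(rng, (emb.n_positions, emb.d_p), dtype=dtype),
            "emb.pos1", frozen_rows=[emb.pad_position_id],
        )
        self.pos2_emb = Parameter(
            uniform_init(rng, (emb.n_positions, emb.d_p), dtype=dtype),
            "emb.pos2", frozen_rows=[emb.pad_position_id],
        )
        self.pos1_emb.value[emb.pad_position_id] = 0.0
        self.pos2_emb.value[emb.pad_position_id] = 0.0

        self.resnet = ResNetEncoder(emb.d_v, config.conv, config.resnet, rng, dtype)
        self.bigru = BiGRU(emb.d_v, config.gru, rng, dtype)
        self.att_res = AttentionPool(config.conv.d_c, rng, dtype)
        self.att_gru = AttentionPool(self.bigru.d_out, rng, dtype)
        self.head = ClassifierHead(self.config.fused_dim, config.n_classes, rng,
                                   dropout=config.dropout, dtype=dtype)
        self._cache = None

    # -- forward ----------------------------------------------------------

    def forward(self, batch: EncodedBatch, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        """Class probabilities (B, r)."""
        dtype = np.dtype(self.config.dtype).type
        X = np.concatenate(
            [
                self.char_emb.value[batch.char_ids],
                self.pos1_emb.value[batch.pos1_ids],
                self.pos2_emb.value[batch.pos2_ids],
            ],
            axis=2,
        ).astype(dtype)
        L = X.shape[1]
        mask = (np.arange(L)[None, :] < batch.lengths[:, None]).astype(dtype)
        H_c = self.resnet.forward(X)
        H_g = self.bigru.forward(X, batch.lengths, mask, train=train, rng=rng)
        self._a_res, S_c = self.att_res.forward(H_c, mask)
        self._a_gru, S_G = self.att_gru.forward(H_g, mask)
        S = fuse(S_c, S_G)
        probs = self.head.forward(S, train=train, rng=rng)
        self._cache = (batch, X.shape)
        return probs

    # -- backward ---------------------------------------------------------

    def backward(self, dlogits: np.ndarray) -> None:
        """Accumulate parameter gradients given d(loss)/d(logits)."""
        batch, x_shape = self._cache
        d_c = self.config.conv.d_c
        dS = self.head.backward(dlogits)
        dH_c = self.att_res.backward(np.ascontiguousarray(dS[:, :d_c]))
        dH_g = self.att_gru.backward(np.ascontiguousarray(dS[:, d_c:]))
        dX = self.resnet.backward(dH_c) + self.bigru.backward(dH_g)
        d_w, d_p = self.config.embedding.d_w, self.config.embedding.d_p
        np.add.at(self.char_emb.grad, batch.char_ids, dX[:, :, :d_w])
        np.add.at(self.pos1_emb.grad, batch.pos1_ids, dX[:, :, d_w : d_w + d_p])
        np.add.at(self.pos2_emb.grad, batch.pos2_ids, dX[:, :, d_w + d_p :])
        for p in self.parameters():
            p.apply_freeze()

    # -- utilities --------------------------------------------------------

    def conv_layer_count(self) -> int:
        return self.resnet.conv_layer_count()

    def parameter_groups(self) -> dict[str, list[Parameter]]:
        """Named parameter groups, e.g. for per-group gradient checks."""
        return {
            "embedding": [self.char_emb, self.pos1_emb, self.pos2_emb],
            "resnet": self.resnet.parameters(),
            "gru": self.bigru.parameters(),
            "attention_res": self.att_res.parameters(),
            "attention_gru": self.att_gru.parameters(),
            "classifier": self.head.parameters(),
        }

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {}
        for i, p in enumerate(self.parameters()):
            out[f"{i}:{p.name}"] = p.value.copy()
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError("state dict does not match the architecture")
        for i, p in enumerate(params):
            key = f"{i}:{p.name}"
            p.value[...] = state[key]
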