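"""Supervised optimization of the hybrid model and batch prediction.

Cross-entropy over the relation categories (UNKNOWN included as a
class), Adam, early stopping on held-out micro-F1.  Published defaults:
batch size 64, learning rate 0.015, dropout 0.5.  For small synthetic
runs the learning rate 1e-3 (``SMALL_RUN_LR``) is the documented
fallback — 0.015 is aggressive at desk scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .corpus import RelationInstance
from .encoding import EmbeddingSpec, EncodedBatch, Vocabulary, build_vocabulary, encode_dataset
from .evaluation import micro_f1
from .nn.model import ModelConfig, RelationModel
from .schema import RELATION_LABELS, UNKNOWN, UNLABELED

#: Documented fallback learning rate for small synthetic runs.
SMALL_RUN_LR = 1e-3

#: Canonical label order for classifier ids: schema order, then UNKNOWN.
CANONICAL_LABEL_ORDER = RELATION_LABELS + (UNKNOWN,)


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 64
    learning_rate: float = 0.015
    optimizer: str = "adam"
    dropout: float = 0.5
    epochs: int = 30
    patience: int = 5
    val_fraction: float = 0.1
    class_weighted: bool = False
    restarts: int = 1  # independent runs; best-by-validation kept
    model: ModelConfig | None = None  # None -> published defaults

    def __post_init__(self) -> None:
        if min(self.batch_size, self.epochs, self.patience) <= 0 or self.learning_rate <= 0:
            raise ValueError("batch_size, epochs, patience, learning_rate must be positive")


@dataclass
class TrainedModel:
    model: RelationModel
    vocab: Vocabulary
    label_names: tuple[str, ...]
    config: TrainConfig
    history: list[dict] = field(default_factory=list)

    @property
    def architecture_hash(self) -> str:
        return self.model.config.architecture_hash()

    @property
    def spec(self) -> EmbeddingSpec:
        return self.model.config.embedding


class Adam:
    def __init__(self, params, lr: float, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _label_vocabulary(instances: list[RelationInstance]) -> tuple[str, ...]:
    present = {inst.label for inst in instances}
    if UNLABELED in present:
        raise ValueError("training set contains UNLABELED instances")
    unknown = [l for l in present if l not in CANONICAL_LABEL_ORDER]
    if unknown:
        raise ValueError(f"labels outside the schema: {sorted(unknown)}")
    return tuple(l for l in CANONICAL_LABEL_ORDER if l in present)


def _stratified_holdout(labels: np.ndarray, fraction: float, rng: np.random.Generator):
    """Per-label validation indices; labels with a single instance stay
    in train."""
    val = []
    for lbl in np.unique(labels):
        idx = np.flatnonzero(labels == lbl)
        n_val = int(round(fraction * len(idx)))
        if len(idx) < 2 or n_val == 0:
            continue
        val.extend(rng.permutation(idx)[:n_val].tolist())
    val = np.array(sorted(val), dtype=np.int64)
    train = np.setdiff1d(np.arange(len(labels)), val)
    return train, val


def _batch_iter(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for i in range(0, n, batch_size):
        yield order[i : i + batch_size]


def train(
    instances: list[RelationInstance],
    config: TrainConfig,
    seed: int = 0,
    vocab: Vocabulary | None = None,
    char_table: np.ndarray | None = None,
    verbose: bool = False,
) -> TrainedModel:
    """Train the full model; returns the best-by-validation checkpoint.

    With ``config.restarts > 1``, that many independent runs (different
    derived seeds) are trained and the one with the best validation
    micro-F1 (validation loss breaking ties) is kept — small training
    sets make single runs high-variance.

    Deterministic given (data, config, seed) and a fixed thread count.
    """
    if config.restarts > 1:
        base = np.random.default_rng(seed)
        runs = []
        for _ in range(config.restarts):
            sub = int(base.integers(2**31))
            runs.append(_train_once(instances, config, sub, vocab, char_table, verbose))
        return max(
            runs, key=lambda t: (t.history[-1]["val_f1"], -t.history[-1]["val_loss"])
        )
    return _train_once(instances, config, seed, vocab, char_table, verbose)


def _train_once(
    instances: list[RelationInstance],
    config: TrainConfig,
    seed: int,
    vocab: Vocabulary | None,
    char_table: np.ndarray | None,
    verbose: bool,
) -> TrainedModel:
    if not instances:
        raise ValueError("training set is empty")
    label_names = _label_vocabulary(instances)
    if len(label_names) < 2:
        raise ValueError("training requires at least 2 distinct labels")
    model_config = config.model or ModelConfig()
    model_config = _with_classes(model_config, len(label_names))
    label_to_id = {l: i for i, l in enumerate(label_names)}

    if vocab is None:
        vocab = build_vocabulary([inst.sentence for inst in instances])
    batch, _ = encode_dataset(instances, vocab, model_config.embedding, label_to_id)

    rng = np.random.default_rng(seed)
    init_rng = np.random.default_rng(rng.integers(2**31))
    drop_rng = np.random.default_rng(rng.integers(2**31))
    model = RelationModel(model_config, len(vocab), init_rng, char_table=char_table)

    train_idx, val_idx = _stratified_holdout(batch.label_ids, config.val_fraction, rng)
    train_batch = batch.take(train_idx)
    val_batch = batch.take(val_idx) if len(val_idx) else train_batch

    weights = np.ones(len(label_names), dtype=np.float64)
    if config.class_weighted:
        counts = np.bincount(train_batch.label_ids, minlength=len(label_names))
        weights = counts.sum() / np.maximum(counts, 1) / len(label_names)

    opt = Adam(model.parameters(), lr=config.learning_rate)
    trained = TrainedModel(model, vocab, label_names, config)
    best_state, best_f1, best_loss, best_epoch = model.state_dict(), -1.0, np.inf, -1
    stall = 0
    n_classes = len(label_names)
    for epoch in range(config.epochs):
        losses = []
        for idx in _batch_iter(len(train_batch), config.batch_size, rng):
            mb = train_batch.take(idx)
            probs = model.forward(mb, train=True, rng=drop_rng)
            B = len(mb)
            p_true = probs[np.arange(B), mb.label_ids]
            w = weights[mb.label_ids]
            loss = float(-(w * np.log(np.maximum(p_true, 1e-12))).mean())
            if not np.isfinite(loss):
                raise FloatingPointError(f"loss diverged (NaN/inf) at epoch {epoch}")
            losses.append(loss)
            onehot = np.zeros((B, n_classes), dtype=probs.dtype)
            onehot[np.arange(B), mb.label_ids] = 1.0
            dlogits = ((probs - onehot) * w[:, None] / B).astype(probs.dtype)
            model.zero_grad()
            model.backward(dlogits)
            opt.step()
        val_f1, val_loss = _validation_score(model, val_batch, label_names)
        trained.history.append(
            {"epoch": epoch, "loss": float(np.mean(losses)),
             "val_f1": val_f1, "val_loss": val_loss}
        )
        if verbose:
            print(f"epoch {epoch}: loss={np.mean(losses):.4f} "
                  f"val_f1={val_f1:.4f} val_loss={val_loss:.4f}")
        # best by micro-F1, validation loss breaking ties: micro-F1 is
        # coarse on small validation splits and can sit at 0 for many
        # epochs while the model is still genuinely improving
        if (val_f1, -val_loss) > (best_f1, -best_loss):
            best_f1, best_loss = val_f1, val_loss
            best_state, best_epoch = model.state_dict(), epoch
            stall = 0
        else:
            stall += 1
            if stall >= config.patience:
                break
    model.load_state_dict(best_state)
    trained.history.append({"epoch": best_epoch, "loss": np.nan, "val_f1": best_f1,
                            "val_loss": best_loss, "best": True})
    return trained


def _with_classes(mc: ModelConfig, n: int) -> ModelConfig:
    from dataclasses import replace

    return replace(mc, n_classes=n) if mc.n_classes != n else mc


def _validation_score(model: RelationModel, batch: EncodedBatch,
                      label_names: tuple[str, ...]) -> tuple[float, float]:
    """(micro-F1 over non-UNKNOWN labels, mean cross-entropy)."""
    probs = _forward_in_chunks(model, batch)
    loss = float(-np.log(np.maximum(
        probs[np.arange(len(batch)), batch.label_ids], 1e-12)).mean())
    pred = [label_names[i] for i in probs.argmax(axis=1)]
    gold = [label_names[i] for i in batch.label_ids]
    reported = tuple(l for l in label_names if l != UNKNOWN)
    if not any(g in reported for g in gold):
        return float(np.mean([p == g for p, g in zip(pred, gold)])), loss
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return micro_f1(pred, gold, labels=reported), loss


def _forward_in_chunks(model: RelationModel, batch: EncodedBatch,
                       chunk: int = 256) -> np.ndarray:
    out = []
    for i in range(0, len(batch), chunk):
        out.append(model.forward(batch.take(np.arange(i, min(i + chunk, len(batch))))))
    return np.concatenate(out, axis=0)


def predict(
    trained: TrainedModel, instances: list[RelationInstance]
) -> list[tuple[str, float]]:
    """Label and confidence (max softmax component) per instance;
    deterministic (dropout off)."""
    if not instances:
        return []
    label_to_id = {l: i for i, l in enumerate(trained.label_names)}
    batch, kept = encode_dataset(instances, trained.vocab,
                                 trained.model.config.embedding, label_to_id)
    if len(kept) != len(instances):
        raise ValueError("some instances could not be encoded with the model's vocabulary")
    probs = _forward_in_chunks(trained.model, batch)
    ids = probs.argmax(axis=1)
    return [
        (trained.label_names[i], float(probs[row, i])) for row, i in enumerate(ids)
    ]
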