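"""Character vocabulary, relative-position indices and instance encoding.

Each character c_i of a sentence is represented by the concatenation of
a character embedding (dimension d_w) and two position embeddings
(dimension d_p each), one per target entity, giving a per-character
vector of dimension d_v = d_w + 2*d_p.  The relative position of
character i to an entity anchored at its first character is i - start,
clipped to [-p_max, p_max] and offset by p_max so table indices are
non-negative; index 2*p_max + 1 is reserved for PAD positions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .corpus import AnnotatedSentence, EntityMention, RelationInstance

PAD, UNK = "<pad>", "<unk>"
PAD_ID, UNK_ID = 0, 1


@dataclass(frozen=True)
class Vocabulary:
    """Character-to-id map with reserved PAD (0) and UNK (1) ids."""

    char_to_id: dict[str, int]

    def __len__(self) -> int:
        return len(self.char_to_id)

    def __getitem__(self, char: str) -> int:
        return self.char_to_id.get(char, UNK_ID)

    @property
    def id_to_char(self) -> list[str]:
        out = [""] * len(self.char_to_id)
        for ch, i in self.char_to_id.items():
            out[i] = ch
        return out


def build_vocabulary(sentences: list[AnnotatedSentence], min_count: int = 1) -> Vocabulary:
    """Map every character occurring >= min_count times to an id.

    Deterministic: ids assigned by descending frequency, ties broken by
    codepoint order.
    """
    if not sentences:
        raise ValueError("cannot build a vocabulary from an empty corpus")
    counts: dict[str, int] = {}
    for sent in sentences:
        for ch in sent.text:
            counts[ch] = counts.get(ch, 0) + 1
    kept = sorted(
        (ch for ch, n in counts.items() if n >= min_count),
        key=lambda ch: (-counts[ch], ch),
    )
    mapping = {PAD: PAD_ID, UNK: UNK_ID}
    for ch in kept:
        mapping[ch] = len(mapping)
    return Vocabulary(mapping)


@dataclass(frozen=True)
class EmbeddingSpec:
    """Dimensions and limits of the embedding layer.

    d_w: character-embedding dimension; d_p: position-embedding
    dimension; p_max: maximum absolute relative distance before
    clipping; L_max: maximum (padded) sentence length.
    """

    d_w: int = 300
    d_p: int = 25
    p_max: int = 100
    L_max: int = 200

    def __post_init__(self) -> None:
        if min(self.d_w, self.d_p, self.p_max, self.L_max) <= 0:
            raise ValueError("all embedding dimensions must be positive")

    @property
    def d_v(self) -> int:
        return self.d_w + 2 * self.d_p

    @property
    def n_positions(self) -> int:
        # distances -p_max..p_max offset to 0..2*p_max, plus a PAD slot
        return 2 * self.p_max + 2

    @property
    def pad_position_id(self) -> int:
        return 2 * self.p_max + 1


def relative_position(i: int, entity: EntityMention, p_max: int = 100) -> int:
    """Signed distance from character i to the entity's first character,
    clipped to [-p_max, p_max]."""
    return int(np.clip(i - entity.start, -p_max, p_max))


@dataclass
class EncodedInstance:
    """Padded id sequences realizing the embedding-layer input."""

    char_ids: np.ndarray  # (L_max,) int64
    pos1_ids: np.ndarray  # (L_max,) int64
    pos2_ids: np.ndarray  # (L_max,) int64
    true_length: int
    label_id: int


class TruncationError(ValueError):
    """Entity span destroyed by truncation to L_max."""


def _truncation_window(sentence_len: int, e1: EntityMention, e2: EntityMention, L_max: int):
    """Window of length <= L_max centered on the two entities."""
    if sentence_len <= L_max:
        return 0, sentence_len
    lo = min(e1.start, e2.start)
    hi = max(e1.end, e2.end)
    if hi - lo > L_max:
        raise TruncationError(
            f"entity pair spans {hi - lo} characters, exceeding L_max={L_max}"
        )
    margin = (L_max - (hi - lo)) // 2
    start = max(0, min(lo - margin, sentence_len - L_max))
    return start, start + L_max


def encode_instance(
    inst: RelationInstance, vocab: Vocabulary, spec: EmbeddingSpec
) -> EncodedInstance:
    """Encode a relation instance into padded (char, pos1, pos2) id rows.

    Position ids are relative_position(...) + p_max; PAD positions get
    the dedicated pad position id.  Raises TruncationError when the
    entity pair cannot fit inside L_max.
    """
    text = inst.sentence.text
    start, stop = _truncation_window(len(text), inst.e1, inst.e2, spec.L_max)
    window = text[start:stop]
    L = len(window)
    char_ids = np.full(spec.L_max, PAD_ID, dtype=np.int64)
    pos1 = np.full(spec.L_max, spec.pad_position_id, dtype=np.int64)
    pos2 = np.full(spec.L_max, spec.pad_position_id, dtype=np.int64)
    for k, ch in enumerate(window):
        i = start + k
        char_ids[k] = vocab[ch]
        pos1[k] = relative_position(i, inst.e1, spec.p_max) + spec.p_max
        pos2[k] = relative_position(i, inst.e2, spec.p_max) + spec.p_max
    return EncodedInstance(char_ids, pos1, pos2, true_length=L, label_id=-1)


@dataclass
class EncodedBatch:
    """Column-stacked encoded instances ready for the model."""

    char_ids: np.ndarray  # (B, L_max)
    pos1_ids: np.ndarray
    pos2_ids: np.ndarray
    lengths: np.ndarray  # (B,)
    label_ids: np.ndarray  # (B,)

    def __len__(self) -> int:
        return self.char_ids.shape[0]

    def take(self, idx: np.ndarray) -> "EncodedBatch":
        return EncodedBatch(
            self.char_ids[idx],
            self.pos1_ids[idx],
            self.pos2_ids[idx],
            self.lengths[idx],
            self.label_ids[idx],
        )


def encode_dataset(
    instances: list[RelationInstance],
    vocab: Vocabulary,
    spec: EmbeddingSpec,
    label_to_id: dict[str, int],
) -> tuple[EncodedBatch, list[int]]:
    """Encode a list of instances; returns the batch and the indices of
    instances kept (those not rejected by truncation)."""
    rows, kept = [], []
    for idx, inst in enumerate(instances):
        try:
            enc = encode_instance(inst, vocab, spec)
        except TruncationError as exc:
            warnings.warn(f"instance {inst.uid} rejected: {exc}", stacklevel=2)
            continue
        enc.label_id = label_to_id.get(inst.label, -1)
        rows.append(enc)
        kept.append(idx)
    if not rows:
        raise ValueError("no instance survived encoding")
    return (
        EncodedBatch(
            np.stack([r.char_ids for r in rows]),
            np.stack([r.pos1_ids for r in rows]),
            np.stack([r.pos2_ids for r in rows]),
            np.array([r.true_length for r in rows], dtype=np.int64),
            np.array([r.label_id for r in rows], dtype=np.int64),
        ),
        kept,
    )


# ---------------------------------------------------------------------------
# skip-gram pretraining of the character table
# ---------------------------------------------------------------------------


def pretrain_char_embeddings(
    sentences: list[AnnotatedSentence],
    vocab: Vocabulary,
    spec: EmbeddingSpec,
    seed: int | None = None,
    window: int = 5,
    epochs: int = 10,
    negatives: int = 5,
    lr: float = 0.025,
) -> np.ndarray:
    """Skip-gram with negative sampling over the corpus characters.

    Returns a (|V|, d_w) table used to initialize the trainable
    character embeddings; the PAD row is all-zero.  Falls back to random
    initialization (with a warning) when the corpus is shorter than the
    context window.
    """
    rng = np.random.default_rng(seed)
    V, d = len(vocab), spec.d_w
    table = rng.uniform(-0.5 / d, 0.5 / d, size=(V, d)).astype(np.float64)
    ids = [np.array([vocab[ch] for ch in s.text], dtype=np.int64) for s in sentences if s.text]
    total = sum(len(a) for a in ids)
    if total <= window:
        warnings.warn("corpus too small for skip-gram window; using random init", stacklevel=2)
        table[PAD_ID] = 0.0
        return table
    ctx = np.zeros((V, d), dtype=np.float64)
    # unigram^0.75 negative-sampling distribution
    counts = np.bincount(np.concatenate(ids), minlength=V).astype(np.float64)
    counts[PAD_ID] = 0.0
    probs = counts**0.75
    probs /= probs.sum()
    for _ in range(epochs):
        for seq in ids:
            n = len(seq)
            for t in range(n):
                w = int(seq[t])
                span = rng.integers(1, window + 1)
                lo, hi = max(0, t - span), min(n, t + span + 1)
                for c in range(lo, hi):
                    if c == t:
                        continue
                    targets = np.empty(negatives + 1, dtype=np.int64)
                    targets[0] = seq[c]
                    targets[1:] = rng.choice(V, size=negatives, p=probs)
                    labels = np.zeros(negatives + 1)
                    labels[0] = 1.0
                    vecs = ctx[targets]  # (k, d)
                    scores = 1.0 / (1.0 + np.exp(-vecs @ table[w]))
                    g = (labels - scores) * lr  # (k,)
                    dw = g @ vecs
                    ctx[targets] += np.outer(g, table[w])
                    table[w] += dw
    table[PAD_ID] = 0.0
    return table


def save_embeddings_text(table: np.ndarray, vocab: Vocabulary, path: str | Path) -> None:
    """Serialize in the word2vec text format: a "|V| d" header, then one
    token and its floats per line."""
    chars = vocab.id_to_char
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{table.shape[0]} {table.shape[1]}\n")
        for i, ch in enumerate(chars):
            fh.write(ch + " " + " ".join(f"{x:.6g}" for x in table[i]) + "\n")


def load_embeddings_text(path: str | Path) -> tuple[np.ndarray, list[str]]:
    with open(path, encoding="utf-8") as fh:
        n, d = map(int, fh.readline().split())
        table = np.zeros((n, d))
        tokens = []
        for i in range(n):
            parts = fh.readline().rstrip("\n").split(" ")
            tokens.append(parts[0])
            table[i] = [float(x) for x in parts[1:]]
    return table, tokens
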