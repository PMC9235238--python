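"""Annotated corpus containers, JSONL I/O and candidate-pair generation.

The corpus format is JSONL, one sentence per line::

    {"sid": ..., "text": ...,
     "entities": [{"id", "type", "start", "end"}, ...],
     "relations": [{"e1", "e2", "label"}, ...]}

Spans are 0-based half-open intervals over Unicode code points.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .schema import ENTITY_TYPES, UNKNOWN, RelationSchema, default_schema

#: Ideographic full stop — the sentence delimiter of clinical narrative.
#: ASCII "." is *not* a boundary (decimal values occur inside sentences).
SENTENCE_DELIMITER = "。"


class CorpusError(ValueError):
    """Malformed or invariant-violating corpus content."""


@dataclass(frozen=True)
class EntityMention:
    """A typed entity mention with a half-open character span."""

    id: str
    etype: str
    start: int
    end: int
    surface: str

    def __post_init__(self) -> None:
        if self.etype not in ENTITY_TYPES:
            raise CorpusError(f"entity {self.id!r}: unknown type {self.etype!r}")
        if not (0 <= self.start < self.end):
            raise CorpusError(f"entity {self.id!r}: bad span [{self.start}, {self.end})")


@dataclass
class AnnotatedSentence:
    """A sentence (character sequence) with entity mentions and gold relations."""

    sid: str
    text: str
    entities: list[EntityMention] = field(default_factory=list)
    gold_relations: list[tuple[str, str, str]] = field(default_factory=list)

    def validate(self, schema: RelationSchema | None = None) -> "AnnotatedSentence":
        schema = schema or default_schema()
        by_id: dict[str, EntityMention] = {}
        for ent in self.entities:
            if ent.id in by_id:
                raise CorpusError(f"sentence {self.sid!r}: duplicate entity id {ent.id!r}")
            if ent.end > len(self.text):
                raise CorpusError(
                    f"sentence {self.sid!r}: span of entity {ent.id!r} "
                    f"[{ent.start}, {ent.end}) exceeds sentence length {len(self.text)}"
                )
            if self.text[ent.start : ent.end] != ent.surface:
                raise CorpusError(
                    f"sentence {self.sid!r}: surface of {ent.id!r} does not match its span"
                )
            by_id[ent.id] = ent
        for e1, e2, label in self.gold_relations:
            for eid in (e1, e2):
                if eid not in by_id:
                    raise CorpusError(
                        f"sentence {self.sid!r}: relation references missing entity {eid!r}"
                    )
            pair = schema.canonical_pair(by_id[e1].etype, by_id[e2].etype)
            if pair is None:
                raise CorpusError(
                    f"sentence {self.sid!r}: ({by_id[e1].etype}, {by_id[e2].etype}) "
                    "is not a schema pair category"
                )
            if label != UNKNOWN and label not in schema.pair_categories[pair]:
                raise CorpusError(
                    f"sentence {self.sid!r}: label {label!r} is not admissible for the "
                    f"{pair[0]}-{pair[1]} pair category"
                )
        return self

    def entity(self, eid: str) -> EntityMention:
        for ent in self.entities:
            if ent.id == eid:
                return ent
        raise KeyError(eid)


@dataclass
class RelationInstance:
    """One (sentence, entity pair, label) classification unit.

    ``e1``/``e2`` are stored in the pair category's canonical type order,
    not textual order.  ``hidden_label`` carries the generator's ground
    truth for drift audits on semi-supervised fixtures; it is never
    serialized and never visible to training.
    """

    sentence: AnnotatedSentence
    e1: EntityMention
    e2: EntityMention
    label: str
    hidden_label: str | None = None

    @property
    def uid(self) -> str:
        return f"{self.sentence.sid}:{self.e1.id}:{self.e2.id}"

    def with_label(self, label: str) -> "RelationInstance":
        return RelationInstance(self.sentence, self.e1, self.e2, label, self.hidden_label)


def segment_sentences(document: str) -> list[str]:
    """Split a document on the ideographic full stop, dropping the
    delimiter and suppressing empty segments."""
    return [seg for seg in document.split(SENTENCE_DELIMITER) if seg]


def _sentence_from_obj(obj: dict, schema: RelationSchema) -> AnnotatedSentence:
    entities = [
        EntityMention(
            id=e["id"],
            etype=e["type"],
            start=int(e["start"]),
            end=int(e["end"]),
            surface=obj["text"][int(e["start"]) : int(e["end"])],
        )
        for e in obj.get("entities", [])
    ]
    relations = [(r["e1"], r["e2"], r["label"]) for r in obj.get("relations", [])]
    return AnnotatedSentence(
        sid=str(obj["sid"]), text=obj["text"], entities=entities, gold_relations=relations
    ).validate(schema)


def load_corpus(path: str | Path, schema: RelationSchema | None = None) -> list[AnnotatedSentence]:
    """Load and validate a JSONL corpus; order is preserved."""
    schema = schema or default_schema()
    sentences: list[AnnotatedSentence] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusError(f"{path}: malformed JSON on line {lineno}: {exc}") from exc
            sentences.append(_sentence_from_obj(obj, schema))
    return sentences


def write_corpus(sentences: list[AnnotatedSentence], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for sent in sentences:
            obj = {
                "sid": sent.sid,
                "text": sent.text,
                "entities": [
                    {"id": e.id, "type": e.etype, "start": e.start, "end": e.end}
                    for e in sent.entities
                ],
                "relations": [
                    {"e1": e1, "e2": e2, "label": lbl} for e1, e2, lbl in sent.gold_relations
                ],
            }
            fh.write(json.dumps(obj, ensure_ascii=False) + "\n")


def generate_candidate_pairs(
    sentence: AnnotatedSentence, schema: RelationSchema | None = None
) -> list[RelationInstance]:
    """Emit one instance per unordered mention pair whose type pair is a
    schema category.

    Pairs matching a gold relation carry its label; all other admissible
    pairs carry UNKNOWN.  (e1, e2) are stored in canonical type order.
    """
    schema = schema or default_schema()
    gold: dict[frozenset[str], str] = {
        frozenset((e1, e2)): lbl for e1, e2, lbl in sentence.gold_relations
    }
    out: list[RelationInstance] = []
    ents = sentence.entities
    for i in range(len(ents)):
        for j in range(i + 1, len(ents)):
            a, b = ents[i], ents[j]
            pair = schema.canonical_pair(a.etype, b.etype)
            if pair is None:
                continue
            # canonical order: the mention whose type matches pair[0] is e1
            e1, e2 = (a, b) if a.etype == pair[0] else (b, a)
            label = gold.get(frozenset((a.id, b.id)), UNKNOWN)
            out.append(RelationInstance(sentence, e1, e2, label))
    return out


def downsample_unknown(
    instances: list[RelationInstance],
    max_ratio: float = 2.0,
    seed: int | None = None,
) -> list[RelationInstance]:
    """Cap UNKNOWN instances at ``max_ratio`` times the non-UNKNOWN count.

    Candidate-pair populations are dominated by "no relation" pairs; a
    bounded negative-to-positive ratio keeps training tractable.
    """
    rng = np.random.default_rng(seed)
    unknown = [inst for inst in instances if inst.label == UNKNOWN]
    known = [inst for inst in instances if inst.label != UNKNOWN]
    cap = int(max_ratio * len(known))
    if len(unknown) <= cap:
        return list(instances)
    keep = rng.choice(len(unknown), size=cap, replace=False)
    kept = [unknown[i] for i in sorted(keep)]
    return known + kept


def split_train_test(
    instances: list[RelationInstance],
    ratio: tuple[float, float] = (0.8, 0.2),
    seed: int | None = None,
) -> tuple[list[RelationInstance], list[RelationInstance]]:
    """Stratified-by-label deterministic split.

    Sizes are within 1 of the exact proportions per label stratum; a
    label with fewer than 2 instances goes to the train side with a
    warning.
    """
    if not instances:
        raise ValueError("cannot split an empty instance list")
    if abs(sum(ratio) - 1.0) > 1e-9:
        raise ValueError(f"ratio {ratio} does not sum to 1")
    rng = np.random.default_rng(seed)
    by_label: dict[str, list[int]] = {}
    for idx, inst in enumerate(instances):
        by_label.setdefault(inst.label, []).append(idx)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for label in sorted(by_label):
        idxs = np.array(by_label[label])
        if len(idxs) < 2:
            warnings.warn(
                f"label {label!r} has fewer than 2 instances; assigned to train",
                stacklevel=2,
            )
            train_idx.extend(idxs.tolist())
            continue
        perm = rng.permutation(len(idxs))
        n_test = int(round(ratio[1] * len(idxs)))
        test_idx.extend(idxs[perm[:n_test]].tolist())
        train_idx.extend(idxs[perm[n_test:]].tolist())
    return (
        [instances[i] for i in sorted(train_idx)],
        [instances[i] for i in sorted(test_idx)],
    )
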