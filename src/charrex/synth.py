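"""Synthetic annotated corpora with planted relation triggers.

The generator emits period-free symbolic sentences over a small
alphabet standing in for characters.  Each sentence holds 2-5 entities
of *distinct* types at random positions over random filler symbols.
For every schema-admissible entity pair, a relation may be planted by
writing the label's trigger — three copies of a label-specific reserved
symbol — strictly between the pair; pairs left triggerless are gold
UNKNOWN.  ``noise_rate`` corrupts exactly one of the three trigger
symbols, so the label stays recoverable from the survivors and the
non-neural trigger oracle remains exact.

Because entity types never repeat within a sentence, a planted trigger
is admissible only for its own pair: the mapping from the inter-entity
substring to the label is deterministic, and empirical class
frequencies track ``class_proportions`` exactly (assignment probability
per pair is scaled by the label mass of its category).  The optional
``nested`` flag (off by default) adds nested mentions and voids both
guarantees.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .corpus import AnnotatedSentence, EntityMention, RelationInstance, generate_candidate_pairs
from .schema import (
    RELATION_COUNTS,
    RELATION_LABELS,
    UNKNOWN,
    UNLABELED,
    RelationSchema,
    default_schema,
)

TRIGGER_LEN = 3


class SynthConfigError(ValueError):
    pass


def _default_proportions() -> dict[str, float]:
    total = sum(RELATION_COUNTS.values())
    return {l: c / total for l, c in RELATION_COUNTS.items()}


@dataclass(frozen=True)
class SynthConfig:
    alphabet_size: int = 60
    n_sentences: int = 100
    sentence_len: tuple[int, int] = (15, 60)
    entity_len: tuple[int, int] = (1, 4)
    entities_per_sentence: tuple[int, int] = (2, 5)
    noise_rate: float = 0.05
    unknown_fraction: float = 0.6
    class_proportions: dict[str, float] = field(default_factory=_default_proportions)
    nested: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alphabet_size < len(RELATION_LABELS) + 12:
            raise SynthConfigError(
                "alphabet too small for trigger + per-type + neutral symbols"
            )
        bad = set(self.class_proportions) - set(RELATION_LABELS)
        if bad:
            raise SynthConfigError(f"unknown labels in class_proportions: {sorted(bad)}")
        lo, hi = self.entities_per_sentence
        if not (2 <= lo <= hi <= 5):
            raise SynthConfigError("entities_per_sentence must lie within [2, 5]")
        # minimal assembly: prefix + 2 shortest entities + 1 gap holding a trigger
        minimal = 1 + 2 * self.entity_len[0] + (TRIGGER_LEN + 2)
        if minimal > self.sentence_len[1]:
            raise SynthConfigError(
                f"sentence_len {self.sentence_len} cannot fit two entities and a trigger "
                f"(needs >= {minimal})"
            )

    @property
    def alphabet(self) -> list[str]:
        return [chr(0x4E00 + i) for i in range(self.alphabet_size)]

    @property
    def trigger_symbols(self) -> dict[str, str]:
        """One reserved symbol per relation label; trigger = symbol * 3."""
        syms = self.alphabet[-len(RELATION_LABELS):]
        return dict(zip(RELATION_LABELS, syms))

    @property
    def type_symbols(self) -> dict[str, list[str]]:
        """Disjoint surface sub-alphabets, one per entity type.

        Clinical mentions are type-recognizable from their surface
        (disease names look like disease names); without this, the
        label would not be a function of the visible text at all —
        only the gold type annotations, which the classifier never
        sees, would disambiguate admissibility.
        """
        pool = self.alphabet[: -len(RELATION_LABELS)]
        per = max(2, (len(pool) // 2) // 5)
        from .schema import ENTITY_TYPES

        return {t: pool[i * per : (i + 1) * per] for i, t in enumerate(ENTITY_TYPES)}

    @property
    def filler_symbols(self) -> list[str]:
        """Neutral symbols for gaps and padding (no type/trigger overlap)."""
        pool = self.alphabet[: -len(RELATION_LABELS)]
        per = max(2, (len(pool) // 2) // 5)
        return pool[5 * per :]

    def normalized_proportions(self) -> dict[str, float]:
        total = sum(self.class_proportions.values())
        if total <= 0:
            raise SynthConfigError("class_proportions must have positive mass")
        return {l: p / total for l, p in self.class_proportions.items()}


def _category_masses(props: dict[str, float], schema: RelationSchema) -> dict[tuple[str, str], float]:
    masses: dict[tuple[str, str], float] = {}
    for lbl, p in props.items():
        cat = schema.category_of(lbl)
        masses[cat] = masses.get(cat, 0.0) + p
    return masses


def _plan_relations(types, config, schema, props, cat_mass, rng):
    """Choose (i, j, label) for admissible index pairs.

    A pair of category c is planted with probability
    n_cats * (1 - unknown_fraction) * mass(c) and labeled within the
    category proportionally, so the marginal label distribution equals
    the normalized class proportions while the expected triggerless
    fraction is unknown_fraction.
    """
    n_cats = len(cat_mass)
    planted = []
    for i in range(len(types)):
        for j in range(i + 1, len(types)):
            cat = schema.canonical_pair(types[i], types[j])
            if cat is None or cat not in cat_mass:
                continue
            p_assign = n_cats * (1.0 - config.unknown_fraction) * cat_mass[cat]
            if p_assign > 1.0:
                warnings.warn(
                    "unknown_fraction too low to honor class proportions exactly",
                    stacklevel=3,
                )
                p_assign = 1.0
            if rng.random() >= p_assign:
                continue
            labels = [l for l in schema.pair_categories[cat] if l in props]
            w = np.array([props[l] for l in labels])
            planted.append((i, j, labels[rng.choice(len(labels), p=w / w.sum())]))
    return planted


def _assemble(types, relations, config, rng):
    """Lay out filler / entities / triggers; returns (text, spans, kept)."""
    filler = config.filler_symbols
    triggers = config.trigger_symbols
    e_lo, e_hi = config.entity_len
    n = len(types)
    ent_lens = rng.integers(e_lo, e_hi + 1, size=n)
    prefix = int(rng.integers(1, 4))
    gap_base = rng.integers(1, 3, size=n - 1) if n > 1 else np.array([], dtype=int)
    kept = list(relations)

    def total_len(lens, gaps, rels):
        return prefix + int(lens.sum()) + int(gaps.sum()) + (TRIGGER_LEN + 1) * len(rels)

    # shrink to fit the sentence budget: drop relations first, then
    # shorten entities and gaps to their minima
    while total_len(ent_lens, gap_base, kept) > config.sentence_len[1]:
        if kept:
            kept.pop(int(rng.integers(len(kept))))
        elif (ent_lens > e_lo).any():
            ent_lens = np.full(n, e_lo)
            gap_base = np.ones_like(gap_base)
        else:
            raise SynthConfigError("sentence budget too small even at minimal layout")

    gap_for = {}  # relation index -> gap index in [i, j-1]
    for k, (i, j, _lbl) in enumerate(kept):
        gap_for[k] = int(rng.integers(i, j))

    type_syms = config.type_symbols

    def rand_filler(m):
        return "".join(filler[c] for c in rng.integers(0, len(filler), size=m))

    def rand_surface(etype, m):
        block = type_syms[etype]
        return "".join(block[c] for c in rng.integers(0, len(block), size=m))

    pieces = [rand_filler(prefix)]
    spans = []
    for idx in range(n):
        start = sum(len(p) for p in pieces)
        surface = rand_surface(types[idx], int(ent_lens[idx]))
        pieces.append(surface)
        spans.append((start, start + len(surface), surface))
        if idx < n - 1:
            pieces.append(rand_filler(int(gap_base[idx])))
            for k, (i, j, lbl) in enumerate(kept):
                if gap_for[k] == idx:
                    trig = list(triggers[lbl] * TRIGGER_LEN)
                    if rng.random() < config.noise_rate:
                        trig[int(rng.integers(TRIGGER_LEN))] = filler[
                            int(rng.integers(len(filler)))
                        ]
                    pieces.append("".join(trig) + rand_filler(1))
    text = "".join(pieces)
    # pad with filler up to at least the minimum sentence length
    target = max(len(text), int(rng.integers(config.sentence_len[0],
                                             config.sentence_len[1] + 1)))
    target = min(target, config.sentence_len[1])
    if len(text) < target:
        text += rand_filler(target - len(text))
    return text, spans, kept


def generate_corpus(config: SynthConfig,
                    schema: RelationSchema | None = None) -> list[AnnotatedSentence]:
    """Deterministic (seeded) corpus with the planted-trigger structure."""
    schema = schema or default_schema()
    props = config.normalized_proportions()
    cat_mass = _category_masses(props, schema)
    rng = np.random.default_rng(config.seed)
    lo, hi = config.entities_per_sentence
    sentences = []
    for s in range(config.n_sentences):
        n_ent = int(rng.integers(lo, hi + 1))
        types = list(rng.choice(5, size=n_ent, replace=False))
        types = [("treatment", "disease", "symptom", "test", "position")[t] for t in types]
        relations = _plan_relations(types, config, schema, props, cat_mass, rng)
        text, spans, kept = _assemble(types, relations, config, rng)
        entities = [
            EntityMention(id=f"T{k + 1}", etype=types[k], start=a, end=b, surface=surf)
            for k, (a, b, surf) in enumerate(spans)
        ]
        gold = []
        for i, j, lbl in kept:
            cat = schema.canonical_pair(types[i], types[j])
            e1, e2 = (entities[i], entities[j]) if types[i] == cat[0] else (entities[j], entities[i])
            gold.append((e1.id, e2.id, lbl))
        sent = AnnotatedSentence(sid=f"S{s:06d}", text=text, entities=entities,
                                 gold_relations=gold)
        if config.nested:
            sent = _add_nested(sent, config, rng)
        sentences.append(sent.validate(schema))
    return sentences


def _add_nested(sent: AnnotatedSentence, config: SynthConfig,
                rng: np.random.Generator) -> AnnotatedSentence:
    """Optionally nest a 1-character position mention inside a long
    entity (emulating the fuzzy-boundary failure mode; voids oracle
    exactness)."""
    long_ents = [e for e in sent.entities if e.end - e.start >= 2 and e.etype != "position"]
    if long_ents and rng.random() < 0.3:
        host = long_ents[int(rng.integers(len(long_ents)))]
        pos = int(rng.integers(host.start, host.end))
        sent.entities.append(
            EntityMention(id=f"T{len(sent.entities) + 1}", etype="position",
                          start=pos, end=pos + 1, surface=sent.text[pos]))
    return sent


# ---------------------------------------------------------------------------
# the non-neural trigger oracle
# ---------------------------------------------------------------------------


def trigger_oracle(inst: RelationInstance, config: SynthConfig,
                   schema: RelationSchema | None = None) -> str:
    """Predict an instance's label by scanning the inter-entity substring
    for an admissible trigger symbol.

    Exact (F1 = 1.0) on default-generated corpora: triggers sit strictly
    between their pair, entity types never repeat within a sentence, and
    corruption leaves at least two of the three trigger symbols intact.
    """
    schema = schema or default_schema()
    left, right = (inst.e1, inst.e2) if inst.e1.start <= inst.e2.start else (inst.e2, inst.e1)
    region = inst.sentence.text[left.end : right.start]
    symbols = config.trigger_symbols
    for lbl in schema.admissible(inst.e1.etype, inst.e2.etype):
        if symbols[lbl] in region:
            return lbl
    return UNKNOWN


# ---------------------------------------------------------------------------
# semi-supervised fixtures
# ---------------------------------------------------------------------------


def corpus_instances(sentences: list[AnnotatedSentence],
                     schema: RelationSchema | None = None) -> list[RelationInstance]:
    schema = schema or default_schema()
    out: list[RelationInstance] = []
    for sent in sentences:
        out.extend(generate_candidate_pairs(sent, schema))
    return out


def _stratified_allocate(by_label: dict[str, list[int]], sizes: tuple[int, ...],
                         rng: np.random.Generator) -> list[list[int]]:
    """Split per-label index pools into len(sizes) disjoint sets of the
    exact requested sizes, proportionally per label; the first set gets
    at least one instance of every label when it can."""
    total = sum(len(v) for v in by_label.values())
    if sum(sizes) > total:
        raise ValueError(f"requested {sum(sizes)} instances but only {total} available")
    pools = {l: list(rng.permutation(idx)) for l, idx in by_label.items()}
    out: list[list[int]] = []
    for s_i, size in enumerate(sizes):
        remaining = sum(len(p) for p in pools.values())
        take: dict[str, int] = {}
        for lbl, pool in sorted(pools.items()):
            share = int(np.floor(size * len(pool) / remaining)) if remaining else 0
            if s_i == 0 and size >= len(by_label) and pool:
                share = max(share, 1)
            take[lbl] = min(share, len(pool))
        # distribute the remainder to the labels with the largest pools
        short = size - sum(take.values())
        for lbl in sorted(pools, key=lambda l: -(len(pools[l]) - take[l])):
            if short <= 0:
                break
            room = len(pools[lbl]) - take[lbl]
            extra = min(room, short)
            take[lbl] += extra
            short -= extra
        chosen: list[int] = []
        for lbl, k in take.items():
            chosen.extend(int(pools[lbl][i]) for i in range(k))
            pools[lbl] = pools[lbl][k:]
        out.append(chosen)
    return out


def make_semisup_fixture(
    config: SynthConfig, n_seed: int, n_unlabeled: int, n_test: int,
    schema: RelationSchema | None = None,
    max_unknown_ratio: float | None = 2.0,
) -> tuple[list[RelationInstance], list[RelationInstance], list[RelationInstance]]:
    """Disjoint label-stratified (seed, unlabeled, test) instance sets.

    Unlabeled instances carry UNLABELED with the generator's truth in
    ``hidden_label`` (drift audits only; never serialized).  The pooled
    candidate instances are UNKNOWN-downsampled to ``max_unknown_ratio``
    times the labeled count first, mirroring the preprocessing default
    for training corpora (None disables).
    """
    schema = schema or default_schema()
    rng = np.random.default_rng(config.seed + 1)
    need = n_seed + n_unlabeled + n_test
    sentences: list[AnnotatedSentence] = []
    instances: list[RelationInstance] = []
    block = 0
    cfg = config
    while len(instances) < need:
        from dataclasses import replace

        n_more = max(32, int(np.ceil((need - len(instances)) / 2.5)))
        cfg = replace(config, n_sentences=n_more, seed=config.seed + 7919 * block)
        batch = generate_corpus(cfg, schema)
        for sent in batch:  # keep sids (hence instance uids) globally unique
            sent.sid = f"B{block}{sent.sid}"
        sentences.extend(batch)
        instances.extend(corpus_instances(batch, schema))
        if max_unknown_ratio is not None:
            from .corpus import downsample_unknown

            instances = downsample_unknown(
                instances, max_ratio=max_unknown_ratio, seed=config.seed + 13
            )
        block += 1
        if block > 200:
            raise SynthConfigError("generator cannot reach the requested instance count")
    by_label: dict[str, list[int]] = {}
    for idx, inst in enumerate(instances):
        by_label.setdefault(inst.label, []).append(idx)
    missing = [l for l in config.normalized_proportions() if not by_label.get(l)]
    if missing:
        warnings.warn(f"classes with zero seed instances: {missing}", stacklevel=2)
    seed_idx, unl_idx, test_idx = _stratified_allocate(
        by_label, (n_seed, n_unlabeled, n_test), rng
    )
    seed_set = [instances[i] for i in seed_idx]
    test_set = [instances[i] for i in test_idx]
    unlabeled = [
        RelationInstance(inst.sentence, inst.e1, inst.e2, UNLABELED,
                         hidden_label=inst.label)
        for inst in (instances[i] for i in unl_idx)
    ]
    return seed_set, unlabeled, test_set
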