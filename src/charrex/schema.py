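"""Relation schema for clinical entity-pair classification.

Five entity types (treatment, disease, symptom, test, position) combine
into seven admissible pair categories, each with a fixed set of relation
labels (11 in total).  Every pair category additionally admits the
reserved ``UNKNOWN`` label ("no relation"), and instances drawn from an
unannotated pool carry ``UNLABELED`` until a model assigns them a label.
"""

from __future__ import annotations

from dataclasses import dataclass, field

ENTITY_TYPES = ("treatment", "disease", "symptom", "test", "position")

#: Reserved label for candidate pairs with no annotated relation.
UNKNOWN = "unknown"
#: Reserved label for instances awaiting a (pseudo-)label.
UNLABELED = "unlabeled"

# Pair category -> admissible relation labels, in canonical (e1, e2) type
# order.  The canonical order is the order the category is named in:
# e.g. a Test-disease instance always stores the test mention as e1.
_PAIR_TABLE: dict[tuple[str, str], tuple[str, ...]] = {
    ("disease", "position"): ("DAP",),
    ("symptom", "position"): ("SAP", "SNAP"),
    ("test", "disease"): ("TeRD",),
    ("test", "position"): ("TeAP", "TeCP"),
    ("test", "symptom"): ("TeRS", "TeAS"),
    ("treatment", "disease"): ("TrAD", "TrRD"),
    ("treatment", "position"): ("TrAP",),
}

#: The 11 relation labels in canonical (pair-category) order.
RELATION_LABELS = tuple(lbl for labels in _PAIR_TABLE.values() for lbl in labels)

#: Annotated-corpus frequency of each relation label, used as the default
#: class proportions of the synthetic generator.
RELATION_COUNTS: dict[str, int] = {
    "DAP": 304,
    "SAP": 518,
    "SNAP": 893,
    "TeRD": 342,
    "TeAP": 1194,
    "TeCP": 572,
    "TeRS": 190,
    "TeAS": 110,
    "TrAD": 679,
    "TrRD": 227,
    "TrAP": 128,
}


@dataclass(frozen=True)
class RelationSchema:
    """Admissibility map from typed entity pairs to relation labels.

    ``pair_categories`` keys are ordered type pairs in canonical order;
    lookups through :meth:`canonical_pair` accept either order.
    """

    pair_categories: dict[tuple[str, str], tuple[str, ...]] = field(
        default_factory=lambda: dict(_PAIR_TABLE)
    )

    def __post_init__(self) -> None:
        seen: dict[str, tuple[str, str]] = {}
        for pair, labels in self.pair_categories.items():
            for lbl in labels:
                if lbl in seen:
                    raise ValueError(f"label {lbl!r} assigned to two pair categories")
                seen[lbl] = pair

    @property
    def labels(self) -> tuple[str, ...]:
        """All non-UNKNOWN relation labels, in canonical order."""
        return tuple(l for ls in self.pair_categories.values() for l in ls)

    def canonical_pair(self, etype_a: str, etype_b: str) -> tuple[str, str] | None:
        """Return the canonical type order for a pair, or None if the
        unordered pair is not a schema category."""
        if (etype_a, etype_b) in self.pair_categories:
            return (etype_a, etype_b)
        if (etype_b, etype_a) in self.pair_categories:
            return (etype_b, etype_a)
        return None

    def admissible(self, etype_a: str, etype_b: str) -> tuple[str, ...]:
        """Non-UNKNOWN labels admissible for the unordered type pair
        (empty if the pair is not a category)."""
        pair = self.canonical_pair(etype_a, etype_b)
        return self.pair_categories[pair] if pair else ()

    def category_of(self, label: str) -> tuple[str, str]:
        for pair, labels in self.pair_categories.items():
            if label in labels:
                return pair
        raise KeyError(label)


def default_schema() -> RelationSchema:
    return RelationSchema()
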