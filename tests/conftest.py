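"""Shared fixtures: hand-built sentences and reduced model configs."""

from __future__ import annotations

import numpy as np
import pytest

from charrex.corpus import AnnotatedSentence, EntityMention
from charrex.nn.model import ModelConfig
from charrex.schema import RELATION_COUNTS


def make_sentence(text, ents, rels=(), sid="S0"):
    """ents: (id, etype, start, end); rels: (e1, e2, label)."""
    entities = [
        EntityMention(id=i, etype=t, start=a, end=b, surface=text[a:b])
        for i, t, a, b in ents
    ]
    return AnnotatedSentence(
        sid=sid, text=text, entities=entities, gold_relations=list(rels)
    ).validate()


@pytest.fixture
def sentence_factory():
    return make_sentence


@pytest.fixture
def tiny_model_config():
    """Miniature architecture for fast training tests."""
    return ModelConfig.reduced(
        n_classes=2, L_max=16, hidden=8, n_filters=8, depth=3, d_w=8, d_p=4, p_max=8
    )


def four_class_proportions():
    """The 4-label restriction used by the desk-scale experiments."""
    labels = ("SAP", "TeRD", "TrAD", "DAP")
    total = sum(RELATION_COUNTS[l] for l in labels)
    return {l: RELATION_COUNTS[l] / total for l in labels}


@pytest.fixture
def rng():
    return np.random.default_rng(0)
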