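"""Schema admissibility, JSONL corpus I/O, candidate pairs, splits."""

import json

import pytest

from charrex.corpus import (
    CorpusError,
    downsample_unknown,
    generate_candidate_pairs,
    load_corpus,
    segment_sentences,
    split_train_test,
    write_corpus,
)
from charrex.schema import RELATION_LABELS, UNKNOWN, default_schema

from conftest import make_sentence


class TestSchema:
    def test_seven_categories_eleven_labels(self):
        schema = default_schema()
        assert len(schema.pair_categories) == 7
        assert len(schema.labels) == 11
        assert set(schema.labels) == set(RELATION_LABELS)

    def test_each_label_in_exactly_one_category(self):
        schema = default_schema()
        seen = [l for labels in schema.pair_categories.values() for l in labels]
        assert len(seen) == len(set(seen))

    def test_canonical_pair_is_order_insensitive(self):
        schema = default_schema()
        assert schema.canonical_pair("disease", "test") == ("test", "disease")
        assert schema.canonical_pair("test", "disease") == ("test", "disease")
        assert schema.canonical_pair("disease", "disease") is None

    @pytest.mark.parametrize(
        "label,pair",
        [("TeRD", ("test", "disease")), ("TrAP", ("treatment", "position")),
         ("SNAP", ("symptom", "position"))],
    )
    def test_category_of(self, label, pair):
        assert default_schema().category_of(label) == pair


class TestSegmentation:
    @pytest.mark.parametrize(
        "doc,expected",
        [
            ("A。B。", ["A", "B"]),
            ("A", ["A"]),
            ("。。", []),
            ("x1.5mg。y", ["x1.5mg", "y"]),  # ASCII '.' is not a boundary
        ],
    )
    def test_split_on_ideographic_full_stop(self, doc, expected):
        assert segment_sentences(doc) == expected


class TestCorpusIO:
    def test_round_trip(self, tmp_path):
        sent = make_sentence(
            "abcdefgh",
            [("T1", "test", 0, 2), ("T2", "disease", 4, 6)],
            [("T1", "T2", "TeRD")],
        )
        path = tmp_path / "c.jsonl"
        write_corpus([sent], path)
        loaded = load_corpus(path)
        assert len(loaded) == 1
        assert loaded[0].text == sent.text
        assert len(loaded[0].entities) == 2
        assert loaded[0].gold_relations == [("T1", "T2", "TeRD")]
        # byte-level round trip up to key ordering
        write_corpus(loaded, tmp_path / "c2.jsonl")
        assert (tmp_path / "c.jsonl").read_text() == (tmp_path / "c2.jsonl").read_text()

    def test_empty_file(self, tmp_path):
        path = tmp_path / "empty.jsonl"
        path.write_text("")
        assert load_corpus(path) == []

    def test_malformed_line_names_line_number(self, tmp_path):
        path = tmp_path / "bad.jsonl"
        path.write_text('{"sid": "S1", "text": "ab", "entities": [], "relations": []}\n{oops\n')
        with pytest.raises(CorpusError, match="line 2"):
            load_corpus(path)

    def test_span_outside_sentence_names_sid(self, tmp_path):
        obj = {"sid": "S9", "text": "ab",
               "entities": [{"id": "T1", "type": "test", "start": 0, "end": 5}],
               "relations": []}
        path = tmp_path / "bad.jsonl"
        path.write_text(json.dumps(obj) + "\n")
        with pytest.raises(CorpusError, match="S9"):
            load_corpus(path)

    def test_inadmissible_label_names_pair_category(self, tmp_path):
        # TrAP belongs to Treatment-position, not Test-disease
        obj = {"sid": "S1", "text": "abcdef",
               "entities": [{"id": "T1", "type": "test", "start": 0, "end": 2},
                            {"id": "T2", "type": "disease", "start": 3, "end": 5}],
               "relations": [{"e1": "T1", "e2": "T2", "label": "TrAP"}]}
        path = tmp_path / "bad.jsonl"
        path.write_text(json.dumps(obj) + "\n")
        with pytest.raises(CorpusError, match="test-disease"):
            load_corpus(path)


class TestCandidatePairs:
    def test_gold_relation_carried(self):
        sent = make_sentence(
            "abcdefgh",
            [("T1", "test", 0, 2), ("T2", "disease", 4, 6)],
            [("T1", "T2", "TeRD")],
        )
        insts = generate_candidate_pairs(sent)
        assert len(insts) == 1
        assert insts[0].label == "TeRD"

    def test_non_schema_pair_not_emitted(self):
        sent = make_sentence(
            "abcdef", [("T1", "disease", 0, 2), ("T2", "disease", 3, 5)]
        )
        assert generate_candidate_pairs(sent) == []

    def test_no_entities(self):
        assert generate_candidate_pairs(make_sentence("abc", [])) == []

    def test_canonical_type_order_overrides_textual_order(self):
        # disease appears first in text, but Test-disease is the canonical order
        sent = make_sentence(
            "abcdefgh", [("T1", "disease", 0, 2), ("T2", "test", 4, 6)]
        )
        (inst,) = generate_candidate_pairs(sent)
        assert inst.e1.etype == "test"
        assert inst.e2.etype == "disease"
        assert inst.label == UNKNOWN

    def test_pair_count_matches_brute_force(self, rng):
        """n_a x n_b instances for a two-type sentence (brute-force count)."""
        for _ in range(20):
            n_a, n_b = rng.integers(1, 4, size=2)
            ents = []
            pos = 0
            for k in range(n_a):
                ents.append((f"A{k}", "test", pos, pos + 1))
                pos += 2
            for k in range(n_b):
                ents.append((f"B{k}", "position", pos, pos + 1))
                pos += 2
            sent = make_sentence("x" * pos, ents)
            insts = generate_candidate_pairs(sent)
            assert len(insts) == n_a * n_b

    def test_every_gold_relation_appears_exactly_once(self):
        sent = make_sentence(
            "abcdefghij",
            [("T1", "test", 0, 1), ("T2", "disease", 2, 3), ("T3", "position", 4, 5)],
            [("T1", "T2", "TeRD"), ("T1", "T3", "TeAP")],
        )
        insts = generate_candidate_pairs(sent)
        non_unknown = [i for i in insts if i.label != UNKNOWN]
        assert sorted(i.label for i in non_unknown) == ["TeAP", "TeRD"]
        # disease-position pair is admissible but unannotated -> UNKNOWN
        assert sum(i.label == UNKNOWN for i in insts) == 1


class TestSplit:
    def _instances(self, labels):
        out = []
        for k, lbl in enumerate(labels):
            sent = make_sentence(
                "abcdefgh", [("T1", "test", 0, 2), ("T2", "disease", 4, 6)],
                [("T1", "T2", lbl)] if lbl != UNKNOWN else [], sid=f"S{k}",
            )
            out.extend(generate_candidate_pairs(sent))
        return out

    def test_exact_proportions(self):
        insts = self._instances(["TeRD"] * 10)
        train, test = split_train_test(insts, (0.8, 0.2), seed=7)
        assert (len(train), len(test)) == (8, 2)

    def test_deterministic(self):
        insts = self._instances(["TeRD"] * 6 + [UNKNOWN] * 4)
        a = split_train_test(insts, (0.8, 0.2), seed=7)
        b = split_train_test(insts, (0.8, 0.2), seed=7)
        assert [i.uid for i in a[0]] == [i.uid for i in b[0]]
        assert [i.uid for i in a[1]] == [i.uid for i in b[1]]

    def test_stratified_within_one(self):
        insts = self._instances(["TeRD"] * 50 + [UNKNOWN] * 50)
        train, test = split_train_test(insts, (0.8, 0.2), seed=3)
        for side, expect in ((train, 40), (test, 10)):
            n_terd = sum(i.label == "TeRD" for i in side)
            assert abs(n_terd - expect) <= 1

    def test_partition_disjoint_exhaustive(self):
        insts = self._instances(["TeRD"] * 7 + [UNKNOWN] * 5)
        train, test = split_train_test(insts, (0.8, 0.2), seed=1)
        uids = sorted(i.uid for i in train) + sorted(i.uid for i in test)
        assert sorted(uids) == sorted(i.uid for i in insts)

    def test_singleton_label_warns_into_train(self):
        insts = self._instances([UNKNOWN] * 5 + ["TeRD"])  # TeRD is a singleton
        with pytest.warns(UserWarning, match="fewer than 2"):
            train, test = split_train_test(insts, (0.8, 0.2), seed=2)
        singleton = [i for i in insts if i.label == "TeRD"][0]
        assert singleton.uid in {i.uid for i in train}

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            split_train_test([], (0.8, 0.2), seed=0)


def test_downsample_unknown_caps_ratio(rng):
    sent = make_sentence(
        "abcdefgh", [("T1", "test", 0, 2), ("T2", "disease", 4, 6)],
        [("T1", "T2", "TeRD")],
    )
    labeled = generate_candidate_pairs(sent)
    unk_sent = make_sentence(
        "abcdefgh", [("T1", "test", 0, 2), ("T2", "disease", 4, 6)], sid="S1"
    )
    unknowns = generate_candidate_pairs(unk_sent) * 10
    out = downsample_unknown(labeled + unknowns, max_ratio=2.0, seed=0)
    assert sum(i.label == UNKNOWN for i in out) == 2 * len(labeled)
    assert all(i.label == "TeRD" for i in out if i.label != UNKNOWN)
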