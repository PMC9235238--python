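"""Self-training driver semantics, traced with stub models.

The stubs replace the neural trainer/predictor so the accept/merge/
retrain arithmetic can be checked exactly and cheaply.
"""

import numpy as np
import pytest

from charrex.bootstrap import (
    BootstrapConfig,
    BootstrapState,
    bootstrap_round,
    run_bootstrap,
)
from charrex.schema import UNKNOWN, UNLABELED
from charrex.synth import SynthConfig, corpus_instances, generate_corpus
from charrex.training import TrainConfig

from conftest import four_class_proportions


def _instances(n_sentences, seed, sid_prefix):
    cfg = SynthConfig(n_sentences=n_sentences, seed=seed,
                      class_proportions=four_class_proportions())
    sentences = generate_corpus(cfg)
    for sent in sentences:  # keep uids distinct across helper corpora
        sent.sid = f"{sid_prefix}{sent.sid}"
    return corpus_instances(sentences)


def _pool(n, seed=0):
    """n UNLABELED instances with hidden truth from the generator."""
    n_sent = max(12, n)
    insts = _instances(n_sent, seed, "U")
    while len(insts) < n:
        n_sent *= 2
        insts = _instances(n_sent, seed, "U")
    out = []
    for inst in insts[:n]:
        u = inst.with_label(UNLABELED)
        u.hidden_label = inst.label
        out.append(u)
    return out


def _seed_set(n=8, seed=1):
    """n labeled instances guaranteed to span >= 2 classes."""
    insts = _instances(max(24, 3 * n), seed, "L")
    known = [i for i in insts if i.label != UNKNOWN]
    unknown = [i for i in insts if i.label == UNKNOWN]
    half = n // 2
    out = known[:half] + unknown[: n - half]
    assert len(out) == n and len({i.label for i in out}) >= 2
    return out


class StubModel:
    def __init__(self, tag):
        self.tag = tag


def make_stub_trainer(counter):
    def trainer(instances, config, seed):
        counter.append(len(instances))
        return StubModel(f"model{len(counter)}")

    return trainer


def constant_predictor(label="SAP", conf=0.9):
    def predictor(model, instances):
        return [(label, conf) for _ in instances]

    return predictor


def tconfig():
    return TrainConfig(epochs=1, model=None)


class TestBootstrapRound:
    def _state(self, n_pool, trainer_calls):
        trainer = make_stub_trainer(trainer_calls)
        seed = _seed_set()
        model = trainer(seed, tconfig(), 0)
        return BootstrapState(list(seed), _pool(n_pool), [], 0, model)

    def test_all_confident_below_trigger_buffers_without_retrain(self):
        """500 confident instances with N_r=1000: buffered, no retrain."""
        calls = []
        state = self._state(500, calls)
        cfg = BootstrapConfig(lam=0.7, retrain_trigger=1000)
        state, log = bootstrap_round(state, tconfig(), cfg,
                                     trainer=make_stub_trainer(calls),
                                     predictor=constant_predictor())
        assert log.accepted == 500
        assert state.sizes() == (8, 0, 500)
        assert not log.retrained and len(calls) == 1  # only the seed train

    def test_no_confident_instances_only_round_counter_moves(self):
        calls = []
        state = self._state(50, calls)
        before = state.sizes()
        cfg = BootstrapConfig(lam=0.7)
        state, log = bootstrap_round(state, tconfig(), cfg,
                                     trainer=make_stub_trainer(calls),
                                     predictor=constant_predictor(conf=0.1))
        assert log.accepted == 0
        assert state.sizes() == before
        assert state.round == 1

    def test_acceptance_capped_at_trigger_and_ranked_by_confidence(self):
        calls = []
        state = self._state(30, calls)
        pool = state.unlabeled
        confs = {inst.uid: 0.71 + 0.01 * (k % 20) for k, inst in enumerate(pool)}

        def predictor(model, instances):
            return [("SAP", confs[i.uid]) for i in instances]

        cfg = BootstrapConfig(lam=0.7, retrain_trigger=10)
        state, log = bootstrap_round(state, tconfig(), cfg,
                                     trainer=make_stub_trainer(calls), predictor=predictor)
        assert log.accepted == 10
        accepted_uids = {i.uid for i in state.labeled} - {i.uid for i in _seed_set()}
        kept_confs = sorted(confs[u] for u in accepted_uids)
        assert min(kept_confs) >= max(
            confs[i.uid] for i in state.unlabeled
        ) - 0.011  # top-confidence block accepted (ties broken by uid)

    def test_merge_and_retrain_at_trigger(self):
        calls = []
        state = self._state(60, calls)
        cfg = BootstrapConfig(lam=0.7, retrain_trigger=50)
        state, log = bootstrap_round(state, tconfig(), cfg,
                                     trainer=make_stub_trainer(calls),
                                     predictor=constant_predictor())
        assert log.retrained
        assert state.sizes() == (58, 10, 0)
        assert calls[-1] == 58  # retrained on the merged labeled set

    def test_pseudo_error_measured_against_hidden_truth(self):
        calls = []
        state = self._state(40, calls)
        cfg = BootstrapConfig(lam=0.7, retrain_trigger=1000)
        state, log = bootstrap_round(state, tconfig(), cfg,
                                     trainer=make_stub_trainer(calls),
                                     predictor=constant_predictor("SAP", 0.99))
        truth = [i.hidden_label for i in state.reliable]
        expected = np.mean([t != "SAP" for t in truth])
        assert log.pseudo_error == pytest.approx(expected)


class TestRunBootstrap:
    def test_empty_pool_returns_seed_model_after_zero_rounds(self):
        calls = []
        model, labeled, logs = run_bootstrap(
            _seed_set(), [], BootstrapConfig(), tconfig(), seed=0,
            trainer=make_stub_trainer(calls), predictor=constant_predictor(),
        )
        assert logs == []
        assert isinstance(model, StubModel)
        assert len(calls) == 1 and calls[0] == 8

    def test_accumulation_trace_1000_1000_500(self):
        """2500 all-confident instances, N_r=1000: merges of 1000, 1000 and a
        500-instance residual merge at termination."""
        calls = []
        model, labeled, logs = run_bootstrap(
            _seed_set(), _pool(2500), BootstrapConfig(lam=0.7, retrain_trigger=1000),
            tconfig(), seed=0,
            trainer=make_stub_trainer(calls), predictor=constant_predictor(),
        )
        assert [lg.accepted for lg in logs] == [1000, 1000, 500]
        assert [lg.retrained for lg in logs] == [True, True, False]
        # trains: seed, 2 round merges, final residual merge
        assert calls == [8, 1008, 2008, 2508]
        assert len(labeled) == 2508
        assert logs[-1].n_unlabeled == 0

    def test_stall_on_pure_noise_pool(self):
        """Uniform confidence 1/r < 0.7 never clears the threshold."""
        calls = []
        with pytest.warns(UserWarning, match="stalled"):
            model, labeled, logs = run_bootstrap(
                _seed_set(), _pool(100), BootstrapConfig(lam=0.7), tconfig(), seed=0,
                trainer=make_stub_trainer(calls),
                predictor=constant_predictor(conf=1 / 12),
            )
        assert len(labeled) == 8
        assert logs[-1].accepted == 0
        assert logs[-1].n_unlabeled == 100

    def test_lambda_at_least_one_accepts_nothing(self):
        with pytest.warns(UserWarning, match="stalled"):
            _, labeled, logs = run_bootstrap(
                _seed_set(), _pool(50), BootstrapConfig(lam=1.0), tconfig(), seed=0,
                trainer=make_stub_trainer([]), predictor=constant_predictor(conf=1.0),
            )
        assert len(labeled) == 8
        assert all(lg.accepted == 0 for lg in logs)

    def test_conservation_and_monotone_shrinkage(self):
        sizes = []

        def predictor(model, instances):
            # confidence decays with the pool, so acceptance shrinks
            return [("SAP", 0.9 if k % 3 else 0.2) for k, _ in enumerate(instances)]

        calls = []
        seed = _seed_set()
        pool = _pool(90)
        model, labeled, logs = run_bootstrap(
            seed, pool, BootstrapConfig(lam=0.7, retrain_trigger=30), tconfig(), seed=0,
            trainer=make_stub_trainer(calls), predictor=predictor,
        )
        total = len(seed) + len(pool)
        last_u = len(pool)
        for lg in logs:
            assert lg.n_labeled + lg.n_unlabeled + lg.n_reliable == total
            assert lg.n_unlabeled <= last_u
            last_u = lg.n_unlabeled

    def test_single_class_seed_rejected(self):
        seed = [i for i in _seed_set(20) if i.label == UNKNOWN][:4]
        with pytest.raises(ValueError, match="2 distinct labels"):
            run_bootstrap(seed, _pool(10), BootstrapConfig(), tconfig(), seed=0,
                          trainer=make_stub_trainer([]), predictor=constant_predictor())

    def test_labeled_instances_in_pool_rejected(self):
        with pytest.raises(ValueError, match="labeled instances"):
            run_bootstrap(_seed_set(), _seed_set(4, seed=9), BootstrapConfig(),
                          tconfig(), seed=0,
                          trainer=make_stub_trainer([]), predictor=constant_predictor())
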