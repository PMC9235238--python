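"""Desk-scale experiment pipelines on the synthetic world.

Published-scale training (75k-sentence corpus, GPU hours) is out of
reach on one CPU, so these pipelines exercise the full method — corpus
generation, candidate pairs, UNKNOWN downsampling, skip-gram
pretraining, supervised training, bootstrapping, evaluation — on a
reduced world: four relation classes (SAP, TeRD, TrAD, DAP — one per
distinct pair category) plus UNKNOWN, trigger noise 2%, and a reduced
model (window-3 depth-5 residual stack, single BiGRU layer).

The reduced position-clipping radius (p_max = 16) reflects that only
characters near the target entities are informative; collapsing all
farther offsets onto the clip boundary makes the position tables far
more sample-efficient than one embedding per exact distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .bootstrap import BootstrapConfig, RoundLog, run_bootstrap
from .corpus import RelationInstance, downsample_unknown
from .encoding import Vocabulary, build_vocabulary, pretrain_char_embeddings
from .evaluation import micro_f1
from .nn.model import ModelConfig
from .schema import RELATION_COUNTS
from .synth import SynthConfig, corpus_instances, generate_corpus, make_semisup_fixture, trigger_oracle
from .training import TrainConfig, TrainedModel, predict, train

REDUCED_LABELS = ("SAP", "TeRD", "TrAD", "DAP")


def reduced_proportions() -> dict[str, float]:
    total = sum(RELATION_COUNTS[l] for l in REDUCED_LABELS)
    return {l: RELATION_COUNTS[l] / total for l in REDUCED_LABELS}


def reduced_world(seed: int, noise_rate: float = 0.02, n_sentences: int = 100) -> SynthConfig:
    return SynthConfig(
        n_sentences=n_sentences,
        seed=seed,
        noise_rate=noise_rate,
        class_proportions=reduced_proportions(),
    )


def recovery_model_config() -> ModelConfig:
    """Reduced architecture for the planted-relation recovery study."""
    return ModelConfig.reduced(
        n_classes=5, L_max=64, hidden=64, n_filters=64, depth=5, d_w=32, d_p=8, p_max=16
    )


def bootstrap_model_config() -> ModelConfig:
    """Slightly wider variant for self-training from 200 seed instances."""
    return replace(
        ModelConfig.reduced(
            n_classes=5, L_max=64, hidden=96, n_filters=96, depth=5,
            d_w=32, d_p=8, p_max=16,
        ),
        dropout=0.25,
    )


@dataclass
class RecoveryResult:
    model_f1: float
    oracle_f1: float
    n_train: int
    n_test: int
    trained: TrainedModel


def planted_recovery(seed: int = 11, n_train: int = 2000, n_test: int = 500,
                     epochs: int = 40, verbose: bool = False) -> RecoveryResult:
    """Train the reduced model on planted-trigger instances and score it
    against the exact non-neural trigger oracle on a held-out split."""
    config = reduced_world(seed, n_sentences=1400)
    instances = downsample_unknown(
        corpus_instances(generate_corpus(config)), max_ratio=2.0, seed=seed
    )
    if len(instances) < n_train + n_test:
        raise ValueError("world too small for the requested split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(instances))
    train_set = [instances[i] for i in order[:n_train]]
    test_set = [instances[i] for i in order[n_train : n_train + n_test]]

    tconfig = TrainConfig(
        batch_size=64, learning_rate=1e-3, epochs=epochs, patience=10,
        model=recovery_model_config(),
    )
    trained = train(train_set, tconfig, seed=seed, verbose=verbose)
    gold = [i.label for i in test_set]
    pred = [p for p, _ in predict(trained, test_set)]
    oracle_pred = [trigger_oracle(i, config) for i in test_set]
    return RecoveryResult(
        model_f1=micro_f1(pred, gold, labels=REDUCED_LABELS),
        oracle_f1=micro_f1(oracle_pred, gold, labels=REDUCED_LABELS),
        n_train=len(train_set),
        n_test=len(test_set),
        trained=trained,
    )


@dataclass
class BootstrapResult:
    seed_f1: float
    final_f1: float
    logs: list[RoundLog]
    n_seed: int
    n_unlabeled: int
    n_test: int
    unlabeled_cleared: bool
    max_drift: float | None
    final_model: TrainedModel = field(repr=False)
    seed_model: TrainedModel = field(repr=False)


def make_adaptive_trainer(vocab: Vocabulary, char_table: np.ndarray):
    """Trainer whose schedule scales with the labeled-set size: small
    seed sets get small batches, long patience and restart selection
    (high single-run variance); grown sets get the larger-batch
    schedule."""

    def trainer(instances: list[RelationInstance], config: TrainConfig, seed: int):
        if len(instances) < 600:
            cfg = replace(config, batch_size=32, epochs=120, patience=30, restarts=3)
        else:
            cfg = replace(config, batch_size=64, epochs=40, patience=8, restarts=1)
        return train(instances, cfg, seed, vocab=vocab, char_table=char_table)

    return trainer


def bootstrap_study(seed: int = 17, n_seed: int = 200, n_unlabeled: int = 2000,
                    n_test: int = 500, train_seed: int = 2) -> BootstrapResult:
    """Self-training from a 200-instance seed set: pretrain character
    embeddings on all record text, train the O-Relation model, and run
    the accept/merge/retrain loop against a fixed held-out test set."""
    config = reduced_world(seed)
    seed_set, unlabeled, test_set = make_semisup_fixture(
        config, n_seed, n_unlabeled, n_test
    )
    sentences = list(
        {i.sentence.sid: i.sentence for i in seed_set + unlabeled + test_set}.values()
    )
    model_config = bootstrap_model_config()
    vocab = build_vocabulary(sentences)
    char_table = pretrain_char_embeddings(
        sentences, vocab, model_config.embedding, seed=seed + 1, epochs=10
    )
    trainer = make_adaptive_trainer(vocab, char_table)
    tconfig = TrainConfig(learning_rate=1e-3, model=model_config)

    seed_model = trainer(seed_set, tconfig, train_seed)
    gold = [i.label for i in test_set]
    seed_pred = [p for p, _ in predict(seed_model, test_set)]
    seed_f1 = micro_f1(seed_pred, gold, labels=REDUCED_LABELS)

    bconfig = BootstrapConfig(lam=0.7, retrain_trigger=1000, max_rounds=50)
    final_model, labeled, logs = run_bootstrap(
        seed_set, unlabeled, bconfig, tconfig, seed=train_seed, trainer=trainer,
        initial_model=seed_model,
    )
    final_pred = [p for p, _ in predict(final_model, test_set)]
    final_f1 = micro_f1(final_pred, gold, labels=REDUCED_LABELS)
    drifts = [lg.pseudo_error for lg in logs if lg.pseudo_error is not None]
    return BootstrapResult(
        seed_f1=seed_f1,
        final_f1=final_f1,
        logs=logs,
        n_seed=len(seed_set),
        n_unlabeled=len(unlabeled),
        n_test=len(test_set),
        unlabeled_cleared=(logs[-1].n_unlabeled == 0 if logs else not unlabeled),
        max_drift=max(drifts) if drifts else None,
        final_model=final_model,
        seed_model=seed_model,
    )
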