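"""Bootstrapping self-training: grow the labeled set from an unlabeled
pool by accepting confident predictions.

Round structure: the current model predicts every instance of the
unlabeled pool U; instances whose confidence exceeds the threshold
lambda (default 0.7) move into the reliable buffer R carrying their
predicted label.  When |R| reaches the retrain trigger (default 1000)
the buffer merges into the labeled set L and the model is retrained
from scratch on the grown L.  The loop ends when U empties, a round
accepts nothing (stall), or max_rounds is hit; any residual buffer is
merged and a final retrain performed.  Pseudo-labels are frozen once
merged (never re-predicted).

On synthetic fixtures whose unlabeled instances carry a hidden true
label, each round also reports the pseudo-label error rate among its
acceptances — the drift signal of self-training.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .corpus import RelationInstance
from .schema import UNKNOWN, UNLABELED
from .training import TrainConfig, TrainedModel, predict as _predict, train as _train


@dataclass(frozen=True)
class BootstrapConfig:
    lam: float = 0.7  # confidence threshold
    retrain_trigger: int = 1000  # |R| that triggers a retrain; 0 = every round
    max_rounds: int = 50
    cap_per_round: int | None = None  # optional acceptance cap per round
    accept_unknown: bool = True  # pseudo-label UNKNOWN like any class
    relabel: bool = False  # merged pseudo-labels are immutable
    warm_start: bool = False  # retrains are from scratch by default

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("threshold lambda must be positive")
        if self.retrain_trigger < 0 or self.max_rounds < 1:
            raise ValueError("retrain_trigger must be >= 0 and max_rounds >= 1")
        if self.relabel:
            raise NotImplementedError("merged pseudo-labels are frozen (relabel: false)")


@dataclass
class RoundLog:
    round: int
    n_labeled: int
    n_unlabeled: int
    n_reliable: int
    accepted: int
    retrained: bool
    acceptance_by_class: dict[str, int] = field(default_factory=dict)
    pseudo_error: float | None = None


@dataclass
class BootstrapState:
    labeled: list[RelationInstance]
    unlabeled: list[RelationInstance]
    reliable: list[RelationInstance]
    round: int
    model: TrainedModel

    def sizes(self) -> tuple[int, int, int]:
        return len(self.labeled), len(self.unlabeled), len(self.reliable)


def _pseudo_error(accepted: list[RelationInstance]) -> float | None:
    audited = [a for a in accepted if a.hidden_label is not None]
    if not audited:
        return None
    wrong = sum(a.label != a.hidden_label for a in audited)
    return wrong / len(audited)


def bootstrap_round(
    state: BootstrapState,
    train_config: TrainConfig,
    config: BootstrapConfig,
    seed: int = 0,
    trainer=None,
    predictor=None,
) -> tuple[BootstrapState, RoundLog]:
    """One accept-then-maybe-retrain round; mutates and returns state."""
    trainer = trainer or _train
    predictor = predictor or _predict
    preds = predictor(state.model, state.unlabeled)
    eligible = [
        (conf, inst.uid, inst, label)
        for inst, (label, conf) in zip(state.unlabeled, preds)
        if conf > config.lam and (config.accept_unknown or label != UNKNOWN)
    ]
    # rank by confidence descending, ties broken by stable instance id;
    # per-round acceptance honors the "at most N" of the algorithm box:
    # capped at the retrain trigger unless an explicit cap overrides it
    eligible.sort(key=lambda t: (-t[0], t[1]))
    cap = config.cap_per_round if config.cap_per_round is not None else (
        config.retrain_trigger or None
    )
    if cap is not None:
        eligible = eligible[:cap]
    accepted_uids = {t[1] for t in eligible}
    accepted = [inst.with_label(label) for _, _, inst, label in eligible]
    state.unlabeled = [i for i in state.unlabeled if i.uid not in accepted_uids]
    state.reliable.extend(accepted)
    state.round += 1

    hist: dict[str, int] = {}
    for inst in accepted:
        hist[inst.label] = hist.get(inst.label, 0) + 1

    retrained = False
    trigger = max(config.retrain_trigger, 1)
    if state.reliable and len(state.reliable) >= trigger:
        state.labeled = state.labeled + state.reliable
        state.reliable = []
        state.model = trainer(state.labeled, train_config, seed)
        retrained = True

    log = RoundLog(
        round=state.round,
        n_labeled=len(state.labeled),
        n_unlabeled=len(state.unlabeled),
        n_reliable=len(state.reliable),
        accepted=len(accepted),
        retrained=retrained,
        acceptance_by_class=hist,
        pseudo_error=_pseudo_error(accepted),
    )
    return state, log


def run_bootstrap(
    seed_set: list[RelationInstance],
    unlabeled: list[RelationInstance],
    config: BootstrapConfig,
    train_config: TrainConfig,
    seed: int = 0,
    trainer=None,
    predictor=None,
    initial_model: TrainedModel | None = None,
) -> tuple[TrainedModel, list[RelationInstance], list[RoundLog]]:
    """Full self-training loop.

    Returns the final model, the final labeled set (seed + accepted
    pseudo-labels) and the per-round log.  ``initial_model`` (already
    trained on the seed set) skips the O-Relation training step.
    """
    trainer = trainer or _train
    predictor = predictor or _predict
    if not seed_set:
        raise ValueError("seed set is empty")
    if len({inst.label for inst in seed_set}) < 2:
        raise ValueError("seed set must contain at least 2 distinct labels")
    bad = [i.uid for i in unlabeled if i.label != UNLABELED]
    if bad:
        raise ValueError(f"unlabeled pool contains labeled instances: {bad[:3]} ...")

    rng = np.random.default_rng(seed)
    seed_train_seed = int(rng.integers(2**31))  # drawn either way: keeps
    if initial_model is None:                   # retrain seeds identical
        initial_model = trainer(seed_set, train_config, seed_train_seed)
    model = initial_model  # O-Relation
    state = BootstrapState(list(seed_set), list(unlabeled), [], 0, model)
    logs: list[RoundLog] = []
    total = sum(state.sizes())

    while state.unlabeled and state.round < config.max_rounds:
        state, log = bootstrap_round(
            state, train_config, config, int(rng.integers(2**31)),
            trainer=trainer, predictor=predictor,
        )
        logs.append(log)
        if sum(state.sizes()) != total:
            raise AssertionError("instance conservation violated")
        if log.accepted == 0:
            warnings.warn(
                f"bootstrap stalled at round {state.round}: no instance cleared "
                f"lambda={config.lam} ({len(state.unlabeled)} remain unlabeled)",
                stacklevel=2,
            )
            break
    if state.unlabeled and state.round >= config.max_rounds:
        warnings.warn(f"bootstrap stopped at max_rounds={config.max_rounds}", stacklevel=2)
    if state.reliable:  # merge the residual buffer and retrain once more
        state.labeled = state.labeled + state.reliable
        state.reliable = []
        state.model = trainer(state.labeled, train_config, int(rng.integers(2**31)))
    return state.model, state.labeled, logs


def round_log_frame(logs: list[RoundLog]):
    """Round log as a DataFrame (round, |L|, |U|, |R|, accepted, retrained)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "round": lg.round,
                "n_labeled": lg.n_labeled,
                "n_unlabeled": lg.n_unlabeled,
                "n_reliable": lg.n_reliable,
                "accepted": lg.accepted,
                "retrained": lg.retrained,
                "pseudo_error": lg.pseudo_error,
            }
            for lg in logs
        ]
    )
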