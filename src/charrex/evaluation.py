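"""Per-class and overall precision/recall/F1 with UNKNOWN excluded.

UNKNOWN ("no relation") is a trainable class but not a reported one: it
contributes to the confusion counts — a non-UNKNOWN gold predicted
UNKNOWN is a false negative for its class, an UNKNOWN gold predicted as
class k is a false positive for k — but has no row of its own, and the
overall numbers are micro-averages pooled over the non-UNKNOWN classes
only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .schema import RELATION_LABELS, UNKNOWN


@dataclass(frozen=True)
class ClassMetrics:
    precision: float
    recall: float
    f1: float
    support: int


@dataclass
class EvalReport:
    per_class: dict[str, ClassMetrics]
    overall: ClassMetrics
    labels: tuple[str, ...] = field(default=RELATION_LABELS)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for lbl in self.labels:
            m = self.per_class[lbl]
            rows.append((lbl, m.precision, m.recall, m.f1, m.support))
        rows.append(("overall", self.overall.precision, self.overall.recall,
                     self.overall.f1, self.overall.support))
        return pd.DataFrame(rows, columns=["label", "precision", "recall", "f1", "support"])


def _prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    if tp + fp == 0 or tp + fn == 0 or tp == 0:
        if (tp + fp == 0 or tp + fn == 0) and (fp or fn):
            warnings.warn("zero denominator in P/R; metric reported as 0", stacklevel=3)
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f1


def evaluate(predictions: list[str], gold: list[str],
             labels: tuple[str, ...] | None = None) -> EvalReport:
    """Pooled-confusion P/R/F1; ``labels`` restricts and orders the
    reported (non-UNKNOWN) classes."""
    if len(predictions) != len(gold):
        raise ValueError(
            f"length mismatch: {len(predictions)} predictions vs {len(gold)} gold labels"
        )
    labels = tuple(labels) if labels is not None else RELATION_LABELS
    if UNKNOWN in labels:
        raise ValueError("the reported label set must not contain UNKNOWN")
    tp = {l: 0 for l in labels}
    fp = {l: 0 for l in labels}
    fn = {l: 0 for l in labels}
    support = {l: 0 for l in labels}
    for pred, g in zip(predictions, gold):
        if g in support:
            support[g] += 1
        if pred == g:
            if g in tp:
                tp[g] += 1
        else:
            if pred in fp:
                fp[pred] += 1
            if g in fn:
                fn[g] += 1
    per_class = {
        l: ClassMetrics(*_prf(tp[l], fp[l], fn[l]), support[l]) for l in labels
    }
    TP, FP, FN = sum(tp.values()), sum(fp.values()), sum(fn.values())
    overall = ClassMetrics(*_prf(TP, FP, FN), sum(support.values()))
    return EvalReport(per_class=per_class, overall=overall, labels=labels)


def macro_average(report: EvalReport) -> ClassMetrics:
    """Unweighted mean of the per-class metrics (alternative aggregate)."""
    ms = list(report.per_class.values())
    n = len(ms)
    return ClassMetrics(
        sum(m.precision for m in ms) / n,
        sum(m.recall for m in ms) / n,
        sum(m.f1 for m in ms) / n,
        report.overall.support,
    )


def micro_f1(predictions: list[str], gold: list[str],
             labels: tuple[str, ...] | None = None) -> float:
    return evaluate(predictions, gold, labels).overall.f1


def report_by_class(report: EvalReport, path=None) -> str:
    """Render one row per relation label plus an overall row; writes CSV
    when ``path`` is given and returns the plain-text table."""
    frame = report.to_frame()
    if path is not None:
        frame.to_csv(path, index=False)
    return frame.to_string(index=False, float_format=lambda x: f"{x:.4f}")


def load_report_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
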