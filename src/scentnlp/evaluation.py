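"""Confusion matrices, macro-averaged metrics, and the healthy-vs-rest
binary collapse.

Macro averaging weighs the three classes equally regardless of support,
which is the right summary under severe class imbalance.  The binary
collapse treats one class (healthy, by default) as the negative class and
pools the rest, exposing the false-negative count that the hierarchical
ensemble is designed to minimize.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .labels import LABEL_TO_INDEX, LABELS


@dataclass
class ConfusionMatrix:
    """3×3 integer counts; rows = gold, columns = predicted, class order
    (healthy, caution, critical)."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (len(LABELS), len(LABELS)):
            raise ValueError("confusion matrix must be 3x3")
        if np.any(self.counts < 0):
            raise ValueError("confusion matrix entries must be >= 0")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class BinaryCollapse:
    tn: int
    fp: int
    fn: int
    tp: int

    @property
    def total(self) -> int:
        return self.tn + self.fp + self.fn + self.tp


@dataclass
class MacroMetrics:
    precision: float
    recall: float
    f1: float
    per_class: dict[str, dict[str, float]]

    def as_percent(self, digits: int = 2) -> dict[str, float]:
        return {
            "precision": round(100 * self.precision, digits),
            "recall": round(100 * self.recall, digits),
            "f1": round(100 * self.f1, digits),
        }


def confusion_matrix(gold: Sequence[str], pred: Sequence[str]) -> ConfusionMatrix:
    """Tally gold vs predicted labels."""
    if len(gold) != len(pred):
        raise ValueError(f"length mismatch: {len(gold)} gold vs {len(pred)} predicted")
    counts = np.zeros((len(LABELS), len(LABELS)), dtype=int)
    for g, p in zip(gold, pred):
        if g not in LABEL_TO_INDEX or p not in LABEL_TO_INDEX:
            raise ValueError(f"unknown label in pair ({g!r}, {p!r})")
        counts[LABEL_TO_INDEX[g], LABEL_TO_INDEX[p]] += 1
    return ConfusionMatrix(counts)


def macro_metrics(cm: ConfusionMatrix) -> MacroMetrics:
    """Per-class precision/recall/F1 and their unweighted means.

    Undefined ratios (0/0) are set to 0, the common macro-averaging
    convention for absent or never-predicted classes.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    counts = cm.counts
    per_class: dict[str, dict[str, float]] = {}
    precisions, recalls, f1s = [], [], []
    for i, lab in enumerate(LABELS):
        tp = counts[i, i]
        pred_total = counts[:, i].sum()
        gold_total = counts[i, :].sum()
        precision = tp / pred_total if pred_total else 0.0
        recall = tp / gold_total if gold_total else 0.0
        f1 = (
            2 * precision * recall / (precision + recall)
            if precision + recall
            else 0.0
        )
        per_class[lab] = {"precision": precision, "recall": recall, "f1": f1}
        precisions.append(precision)
        recalls.append(recall)
        f1s.append(f1)
    return MacroMetrics(
        precision=float(np.mean(precisions)),
        recall=float(np.mean(recalls)),
        f1=float(np.mean(f1s)),
        per_class=per_class,
    )


def binary_collapse(cm: ConfusionMatrix, negative_class: str = "healthy") -> BinaryCollapse:
    """Collapse the 3×3 matrix to TN/FP/FN/TP for a designated negative
    class; the total is conserved."""
    if negative_class not in LABEL_TO_INDEX:
        raise ValueError(f"unknown class {negative_class!r}")
    neg = LABEL_TO_INDEX[negative_class]
    pos = [i for i in range(len(LABELS)) if i != neg]
    counts = cm.counts
    return BinaryCollapse(
        tn=int(counts[neg, neg]),
        fp=int(counts[pos, :][:, neg].sum()),
        fn=int(counts[neg, pos].sum()),
        tp=int(counts[np.ix_(pos, pos)].sum()),
    )


def evaluation_report(gold: Sequence[str], pred: Sequence[str]) -> dict:
    """JSON-serializable report: confusion matrix, per-class and macro
    metrics (percentages to 2 decimals), healthy-negative binary collapse."""
    cm = confusion_matrix(gold, pred)
    metrics = macro_metrics(cm)
    collapse = binary_collapse(cm, "healthy")
    return {
        "n_documents": cm.total,
        "confusion_matrix": {
            "labels": list(LABELS),
            "counts": cm.counts.tolist(),
        },
        "macro": metrics.as_percent(),
        "per_class": {
            lab: {k: round(100 * v, 2) for k, v in vals.items()}
            for lab, vals in metrics.per_class.items()
        },
        "healthy_negative_collapse": {
            "tn": collapse.tn,
            "fp": collapse.fp,
            "fn": collapse.fn,
            "tp": collapse.tp,
        },
    }


def format_report(report: dict) -> str:
    """Human-readable text table for an evaluation report."""
    lines = [f"documents evaluated: {report['n_documents']}", ""]
    lines.append("confusion matrix (rows gold, cols predicted)")
    header = "            " + "".join(f"{lab:>10}" for lab in report["confusion_matrix"]["labels"])
    lines.append(header)
    for lab, row in zip(
        report["confusion_matrix"]["labels"], report["confusion_matrix"]["counts"]
    ):
        lines.append(f"{lab:>12}" + "".join(f"{c:>10}" for c in row))
    lines.append("")
    lines.append("class        precision   recall       f1")
    for lab, vals in report["per_class"].items():
        lines.append(
            f"{lab:>12}{vals['precision']:>10.2f}{vals['recall']:>9.2f}{vals['f1']:>9.2f}"
        )
    m = report["macro"]
    lines.append(f"{'macro':>12}{m['precision']:>10.2f}{m['recall']:>9.2f}{m['f1']:>9.2f}")
    c = report["healthy_negative_collapse"]
    lines.append("")
    lines.append(
        f"healthy-negative collapse: TN={c['tn']} FP={c['fp']} FN={c['fn']} TP={c['tp']}"
    )
    return "\n".join(lines)
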