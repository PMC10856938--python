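"""Evaluation metrics with an abstention ("uncertain") outcome.

The confusion matrix has the 3 true classes as rows and 4 decision
columns — the 3 classes plus uncertain.  Per class c:

    TP = counts[c, c]          FP = sum over other rows of column c
    FN = row_sum(c) - TP       (abstentions count as FN, never FP)

    precision = TP / (TP + FP)      recall = TP / (TP + FN)
    F1 = 2 * precision * recall / (precision + recall)
    accuracy = sum_c TP_c / total

with the 0/0 := 0 convention throughout.  Abstentions therefore always
count against accuracy and recall; a ``recall_excluding_uncertain``
variant (abstained windows dropped from the denominator) is also
reported for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import CLASS_LABELS, UNCERTAIN

DECISIONS = CLASS_LABELS + (UNCERTAIN,)


def _safe_div(a: float, b: float) -> float:
    return a / b if b else 0.0


def metrics_from_counts(tp: int, fp: int, tn: int, fn: int) -> dict:
    """Precision, recall, F1 and accuracy from outcome counts."""
    if min(tp, fp, tn, fn) < 0:
        raise ValueError("counts must be non-negative")
    precision = _safe_div(tp, tp + fp)
    recall = _safe_div(tp, tp + fn)
    f1 = _safe_div(2 * precision * recall, precision + recall)
    accuracy = _safe_div(tp + tn, tp + fp + tn + fn)
    return {"precision": precision, "recall": recall, "f1": f1, "accuracy": accuracy}


@dataclass
class ConfusionReport:
    counts: np.ndarray  # (3 true, 4 decided)
    row_percent: np.ndarray
    per_class: dict  # label -> dict with tp/fp/tn/fn + precision/recall/f1
    accuracy: float
    labels: tuple = CLASS_LABELS
    decisions: tuple = DECISIONS

    def to_markdown(self) -> str:
        """Row-percent table with a per-class F1 row, for eyeball comparison."""
        head = "| | " + " | ".join(d.capitalize() for d in self.decisions) + " |"
        sep = "|---" * (len(self.decisions) + 1) + "|"
        rows = [head, sep]
        for i, lab in enumerate(self.labels):
            cells = " | ".join(f"{v:.1f}%" for v in self.row_percent[i])
            rows.append(f"| {lab.capitalize()} | {cells} |")
        f1s = " | ".join(f"{self.per_class[lab]['f1']:.2f}" for lab in self.labels)
        rows.append(f"| F1 Score | {f1s} |  |")
        rows.append(f"\nAccuracy: {self.accuracy:.4f}")
        return "\n".join(rows)


def confusion(true_labels, decided_labels) -> ConfusionReport:
    """Tally a confusion report from per-window truth and decisions.

    ``decided_labels`` may contain :data:`UNCERTAIN`; truth may not.
    """
    t = list(true_labels)
    d = list(decided_labels)
    if not t:
        raise ValueError("empty input")
    if len(t) != len(d):
        raise ValueError(f"{len(t)} labels vs {len(d)} decisions")
    li = {c: i for i, c in enumerate(CLASS_LABELS)}
    di = {c: i for i, c in enumerate(DECISIONS)}
    counts = np.zeros((len(CLASS_LABELS), len(DECISIONS)), dtype=int)
    for a, b in zip(t, d):
        if a not in li:
            raise ValueError(f"unknown true label {a!r}")
        if b not in di:
            raise ValueError(f"unknown decision {b!r}")
        counts[li[a], di[b]] += 1

    row_sums = counts.sum(axis=1)
    row_percent = 100.0 * counts / np.where(row_sums == 0, 1, row_sums)[:, None]
    total = counts.sum()
    per_class = {}
    for c, lab in enumerate(CLASS_LABELS):
        tp = int(counts[c, c])
        fp = int(counts[:, c].sum() - tp)
        fn = int(row_sums[c] - tp)
        tn = int(total - tp - fp - fn)
        m = metrics_from_counts(tp, fp, tn, fn)
        decided = int(row_sums[c] - counts[c, di[UNCERTAIN]])
        m["recall_excluding_uncertain"] = _safe_div(tp, decided)
        per_class[lab] = {"tp": tp, "fp": fp, "tn": tn, "fn": fn, **m}
    accuracy = float(np.trace(counts[:, : len(CLASS_LABELS)])) / total
    return ConfusionReport(counts=counts, row_percent=row_percent,
                           per_class=per_class, accuracy=accuracy)
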