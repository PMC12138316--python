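"""Evaluation metrics for binary misinformation classifiers.

Positive class is "fake" (label 1) throughout, which matches a fake-heavy
test set where high recall on fake is the operationally important number.
Undefined ratios (e.g. precision with no positive predictions) are reported
as absent with a reason, never silently as zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

__all__ = [
    "MetricsReport",
    "confusion_and_metrics",
    "roc_auc",
    "comparison_report",
    "render_percent",
]


class MetricsError(ValueError):
    pass


@dataclass
class MetricsReport:
    """Confusion matrix plus the derived scalar metrics.

    ``confusion`` rows are truth (0 = genuine, 1 = fake), columns are
    prediction.  A metric that is undefined for the given confusion table is
    ``None`` with an explanation in ``undefined``.
    """

    confusion: np.ndarray
    n: int
    accuracy: float
    precision: float | None
    recall: float | None
    f1: float | None
    auc: float | None = None
    positive_class: int = 1
    undefined: dict[str, str] = field(default_factory=dict)


def confusion_and_metrics(truth: Sequence[int], pred: Sequence[int]) -> MetricsReport:
    """Accuracy, fake-class precision/recall/F1 and the confusion table."""
    t = np.asarray(truth, dtype=int)
    p = np.asarray(pred, dtype=int)
    if t.shape != p.shape:
        raise MetricsError(f"length mismatch: {t.shape} truth vs {p.shape} predictions")
    if t.size < 1:
        raise MetricsError("need at least one observation")
    conf = np.zeros((2, 2), dtype=int)
    for ti, pi in zip(t, p):
        conf[ti, pi] += 1
    tn, fp = conf[0]
    fn, tp = conf[1]
    n = int(conf.sum())
    undefined: dict[str, str] = {}
    accuracy = (tp + tn) / n
    precision = tp / (tp + fp) if tp + fp else None
    if precision is None:
        undefined["precision"] = "no positive predictions (TP + FP = 0)"
    recall = tp / (tp + fn) if tp + fn else None
    if recall is None:
        undefined["recall"] = "no positive ground-truth items (TP + FN = 0)"
    if precision is None or recall is None or precision + recall == 0:
        f1 = None
        undefined["f1"] = "precision and/or recall undefined or both zero"
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return MetricsReport(conf, n, accuracy, precision, recall, f1, undefined=undefined)


def roc_auc(scores: Sequence[float], truth: Sequence[int]) -> float:
    """Area under the ROC curve for the fake class.

    Equals the Mann-Whitney probability that a random fake item outscores a
    random genuine item, with ties credited one half.
    """
    t = np.asarray(truth, dtype=int)
    if len(np.unique(t)) < 2:
        raise MetricsError("AUC is undefined when only one class is present")
    return float(roc_auc_score(t, np.asarray(scores, dtype=float)))


def render_percent(x: float) -> str:
    return f"{100.0 * x:.2f}"


def comparison_report(
    methods: Mapping[str, tuple[Sequence[int], Sequence[float] | None]],
    truth: Sequence[int],
    csv_path: str | Path | None = None,
    json_path: str | Path | None = None,
) -> pd.DataFrame:
    """One row per method with the five metrics rendered as percentages.

    ``methods`` maps a method name to ``(predictions, scores_or_None)``;
    when scores are absent the AUC column renders N/A.  Rows are sorted by
    method name so the table is independent of insertion order.
    """
    if not methods:
        raise MetricsError("need at least one method")
    rows = []
    for name in sorted(methods):
        pred, scores = methods[name]
        rep = confusion_and_metrics(truth, pred)
        rep.auc = roc_auc(scores, truth) if scores is not None else None
        rows.append(
            {
                "model": name,
                "accuracy": render_percent(rep.accuracy),
                "precision": render_percent(rep.precision) if rep.precision is not None else "N/A",
                "recall": render_percent(rep.recall) if rep.recall is not None else "N/A",
                "f1": render_percent(rep.f1) if rep.f1 is not None else "N/A",
                "auc": render_percent(rep.auc) if rep.auc is not None else "N/A",
            }
        )
    table = pd.DataFrame(rows)
    if csv_path is not None:
        table.to_csv(csv_path, index=False)
    if json_path is not None:
        Path(json_path).write_text(json.dumps(table.to_dict(orient="records"), indent=1))
    return table
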