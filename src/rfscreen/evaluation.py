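"""Classification metric panel: recall, precision, F-score, ROC area, accuracy.

Active compounds are the positive class.  The ROC area is computed from
per-compound ranking scores (vote fractions) via the Mann-Whitney rank-sum
identity: the probability that a uniformly random active scores above a
uniformly random inactive, with ties counted one half.  Ratios with a zero
denominator (e.g. precision when nothing was predicted active) are reported
as NaN with a warning, never silently as zero.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.stats import rankdata

from .descriptors import ACTIVE, FeatureTable
from .forest import ForestModel
from .screening import predict_forest

logger = logging.getLogger("rfscreen")


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricsReport:
    recall: float
    precision: float
    f_score: float
    roc_area: float
    accuracy: float
    n: int
    n_active: int

    def to_dict(self) -> dict:
        def _clean(x: float) -> Optional[float]:
            return None if (x is None or math.isnan(x)) else float(x)

        return {
            "recall": _clean(self.recall),
            "precision": _clean(self.precision),
            "f_score": _clean(self.f_score),
            "roc_area": _clean(self.roc_area),
            "accuracy": _clean(self.accuracy),
            "n": self.n,
            "n_active": self.n_active,
        }

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def to_text(self) -> str:
        """Aligned one-row table in the canonical column order."""
        headers = ["Recall", "Precision", "F-score", "ROC area", "Accuracy"]
        values = [self.recall, self.precision, self.f_score, self.roc_area, self.accuracy]
        cells = ["   nan" if math.isnan(v) else f"{v:6.3f}" for v in values]
        head = "  ".join(f"{h:>9}" for h in headers)
        row = "  ".join(f"{c:>9}" for c in cells)
        return head + "\n" + row


def confusion(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    """Confusion counts with active (=1) as the positive class."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.size == 0:
        raise ValueError("cannot evaluate an empty prediction set")
    if y_true.shape != y_pred.shape:
        raise ValueError(f"label length mismatch: {y_true.shape} vs {y_pred.shape}")
    pos = y_true == ACTIVE
    pred_pos = y_pred == ACTIVE
    return ConfusionCounts(
        tp=int(np.sum(pos & pred_pos)),
        fp=int(np.sum(~pos & pred_pos)),
        tn=int(np.sum(~pos & ~pred_pos)),
        fn=int(np.sum(pos & ~pred_pos)),
    )


def roc_area_from_scores(y_true: np.ndarray, scores: np.ndarray) -> float:
    """Mann-Whitney ROC area: P(score_active > score_inactive) + 0.5 P(tie)."""
    y_true = np.asarray(y_true, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if y_true.shape != scores.shape:
        raise ValueError("scores/labels length mismatch")
    n_pos = int(np.sum(y_true == ACTIVE))
    n_neg = y_true.size - n_pos
    if n_pos == 0 or n_neg == 0:
        logger.warning("ROC area undefined: only one class present")
        return float("nan")
    ranks = rankdata(scores)  # average ranks handle ties as 1/2
    rank_sum_pos = float(np.sum(ranks[y_true == ACTIVE]))
    u = rank_sum_pos - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)


def compute_metrics(
    c: ConfusionCounts,
    scores: Optional[np.ndarray] = None,
    y_true: Optional[np.ndarray] = None,
) -> MetricsReport:
    """Assemble the metric panel from confusion counts and optional scores."""
    nan = float("nan")

    def _ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            logger.warning("%s undefined (zero denominator); reported as NaN", name)
            return nan
        return num / den

    recall = _ratio(c.tp, c.tp + c.fn, "recall")
    precision = _ratio(c.tp, c.tp + c.fp, "precision")
    accuracy = _ratio(c.tp + c.tn, c.total, "accuracy")
    if math.isnan(recall) or math.isnan(precision) or (precision + recall) == 0:
        if not (math.isnan(recall) or math.isnan(precision)):
            logger.warning("f_score undefined (precision + recall = 0); reported as NaN")
        f_score = nan
    else:
        f_score = 2 * precision * recall / (precision + recall)
    if scores is not None:
        if y_true is None:
            raise ValueError("y_true is required to compute the ROC area from scores")
        roc = roc_area_from_scores(y_true, scores)
    else:
        roc = nan
    return MetricsReport(
        recall=recall,
        precision=precision,
        f_score=f_score,
        roc_area=roc,
        accuracy=accuracy,
        n=c.total,
        n_active=c.tp + c.fn,
    )


def evaluate_model(model: ForestModel, table: FeatureTable) -> MetricsReport:
    """Predict a labelled table with the forest and compute the metric panel."""
    if table.labels is None:
        raise ValueError("evaluation requires a labelled feature table")
    labels, tallies = predict_forest(model, table)
    scores = np.array([t.score for t in tallies])
    c = confusion(table.labels, labels)
    return compute_metrics(c, scores=scores, y_true=table.labels)
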