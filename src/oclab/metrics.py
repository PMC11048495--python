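"""Confusion-matrix metrics for imbalanced binary evaluation.

The headline metric is G-means, the geometric mean of recall (minority-class
sensitivity) and specificity (majority-class true-negative rate): it is high
only when *both* classes are recognised, which is what makes it the right
summary on heavily imbalanced data where accuracy saturates.

Conventions: ``positive`` is the minority / non-target class throughout.
Metrics with a zero denominator are reported as ``None`` (serialized as JSON
null), never as NaN arithmetic.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import roc_auc_score

from .exceptions import ConfigError
from .datasets import POSITIVE


@dataclass(frozen=True)
class ConfusionCounts:
    """Raw confusion counts with the minority class as positive."""

    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class EvaluationReport:
    """Derived metrics for one evaluation; ``None`` marks undefined values."""

    counts: ConfusionCounts
    accuracy: float | None
    precision: float | None
    recall: float | None
    specificity: float | None
    gmeans: float | None
    auc: float | None = None

    def to_dict(self) -> dict:
        return {
            "counts": {
                "TP": self.counts.TP,
                "TN": self.counts.TN,
                "FP": self.counts.FP,
                "FN": self.counts.FN,
            },
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "specificity": self.specificity,
            "gmeans": self.gmeans,
            "auc": self.auc,
        }


def confusion(y_true, y_pred, positive: str = POSITIVE) -> ConfusionCounts:
    """Count TP/TN/FP/FN with the given positive label."""
    y_true = np.asarray(y_true, dtype=object)
    y_pred = np.asarray(y_pred, dtype=object)
    if y_true.shape != y_pred.shape:
        raise ConfigError("y_true and y_pred must have equal length")
    t = y_true == positive
    p = y_pred == positive
    return ConfusionCounts(
        TP=int(np.sum(t & p)),
        TN=int(np.sum(~t & ~p)),
        FP=int(np.sum(~t & p)),
        FN=int(np.sum(t & ~p)),
    )


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def gmeans(recall: float, specificity: float) -> float:
    """Geometric mean ``sqrt(recall * specificity)``.

    Both arguments must lie in [0, 1].
    """
    if not (0.0 <= recall <= 1.0 and 0.0 <= specificity <= 1.0):
        raise ConfigError("recall and specificity must lie in [0, 1]")
    return math.sqrt(recall * specificity)


def compute_metrics(counts: ConfusionCounts) -> EvaluationReport:
    """Derive accuracy/precision/recall/specificity/G-means from counts.

    Zero-denominator metrics come back as ``None``; G-means is ``None``
    whenever recall or specificity is.
    """
    if counts.total <= 0:
        raise ConfigError("cannot compute metrics for zero evaluated points")
    recall = _ratio(counts.TP, counts.TP + counts.FN)
    specificity = _ratio(counts.TN, counts.TN + counts.FP)
    gm = gmeans(recall, specificity) if recall is not None and specificity is not None else None
    return EvaluationReport(
        counts=counts,
        accuracy=(counts.TP + counts.TN) / counts.total,
        precision=_ratio(counts.TP, counts.TP + counts.FP),
        recall=recall,
        specificity=specificity,
        gmeans=gm,
    )


def auc(y_true, scores, higher_is_positive: bool = True,
        positive: str = POSITIVE) -> float | None:
    """Rank-based (Mann-Whitney) AUC; ties count 0.5.

    Returns ``None`` when only one class is present. ``higher_is_positive``
    says whether large scores indicate the positive (minority) class.
    """
    y_true = np.asarray(y_true, dtype=object)
    scores = np.asarray(scores, dtype=float)
    if y_true.shape != scores.shape:
        raise ConfigError("y_true and scores must have equal length")
    y = (y_true == positive)
    if y.all() or (~y).all():
        return None
    s = scores if higher_is_positive else -scores
    # roc_auc_score chokes on +/-inf sentinels; AUC is rank-based, so
    # replacing scores by their (tie-averaged) ranks leaves it unchanged.
    if not np.isfinite(s).all():
        if np.isnan(s).any():
            raise ConfigError("scores contain NaN")
        s = rankdata(s)
    return float(roc_auc_score(y.astype(int), s))


def truncate(value: float, decimals: int = 3) -> float:
    """Truncate (round toward zero) to the given number of decimals.

    Printed result tables are truncated rather than rounded; this mirrors
    that presentation rule. Internal computation never truncates.
    """
    factor = 10 ** decimals
    return math.trunc(value * factor) / factor
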