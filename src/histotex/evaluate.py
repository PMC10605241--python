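"""Confusion-matrix metrics, ROC/AUC, and significance testing of AUC differences.

GBM is the positive class throughout. Scores are compared at the fixed 0.5
threshold (scores exactly at 0.5 count as GBM); the ROC curve is the
empirical threshold sweep with trapezoidal AUC, which coincides with the
Mann–Whitney statistic under the half-credit tie convention.

Differences between ROC curves are tested with DeLong's nonparametric
method: the paired variant uses the structural-component covariance of the
two correlated AUCs, the unpaired variant adds independent variances. The
squared z statistic is reported as a 1-df chi-square.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _roc_curve

from .classify import POSITIVE, SCORE_THRESHOLD

__all__ = [
    "ConfusionMatrix",
    "EvalReport",
    "ROCCurve",
    "confusion",
    "metrics",
    "roc_auc",
    "evaluate_scores",
    "compare_roc",
]


@dataclass
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class ROCCurve:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


@dataclass
class EvalReport:
    """Scalar performance summary; ratios with empty denominators are 0 and flagged."""

    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    recall: float
    f1: float
    auc: float | None
    confusion: ConfusionMatrix
    undefined: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["confusion"] = asdict(self.confusion)
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def to_frame(self) -> pd.DataFrame:
        d = self.to_dict()
        d.pop("confusion")
        d.pop("undefined")
        return pd.DataFrame([d])


def _positive_mask(labels) -> np.ndarray:
    return np.asarray(labels).astype(str) == POSITIVE


def confusion(scores, labels) -> ConfusionMatrix:
    """Counts at the 0.5 threshold (score >= 0.5 predicts GBM)."""
    scores = np.asarray(scores, dtype=float)
    if scores.shape[0] != len(labels):
        raise ValueError("scores and labels must have equal length")
    pos = _positive_mask(labels)
    pred_pos = scores >= SCORE_THRESHOLD
    return ConfusionMatrix(
        tp=int((pred_pos & pos).sum()),
        fp=int((pred_pos & ~pos).sum()),
        tn=int((~pred_pos & ~pos).sum()),
        fn=int((~pred_pos & pos).sum()),
    )


def _ratio(num: int, den: int, name: str, undefined: list[str]) -> float:
    if den == 0:
        undefined.append(name)
        return 0.0
    return num / den


def metrics(cm: ConfusionMatrix, auc_value: float | None = None) -> EvalReport:
    """Accuracy, sensitivity, specificity, precision, recall and F1 from counts."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    undefined: list[str] = []
    sens = _ratio(cm.tp, cm.tp + cm.fn, "sensitivity", undefined)
    spec = _ratio(cm.tn, cm.tn + cm.fp, "specificity", undefined)
    prec = _ratio(cm.tp, cm.tp + cm.fp, "precision", undefined)
    if prec + sens == 0:
        undefined.append("f1")
        f1 = 0.0
    else:
        f1 = 2 * prec * sens / (prec + sens)
    return EvalReport(
        accuracy=(cm.tp + cm.tn) / cm.total,
        sensitivity=sens,
        specificity=spec,
        precision=prec,
        recall=sens,
        f1=f1,
        auc=auc_value,
        confusion=cm,
        undefined=undefined,
    )


def roc_auc(scores, labels) -> ROCCurve:
    """Empirical ROC by threshold sweep with trapezoidal AUC."""
    scores = np.asarray(scores, dtype=float)
    pos = _positive_mask(labels)
    if pos.all() or (~pos).all():
        raise ValueError("ROC needs both classes present")
    fpr, tpr, thr = _roc_curve(pos.astype(int), scores)
    return ROCCurve(thresholds=thr, fpr=fpr, tpr=tpr, auc=float(_trapezoid_auc(fpr, tpr)))


def evaluate_scores(scores, labels) -> EvalReport:
    """Full report (confusion metrics + AUC when both classes are present)."""
    cm = confusion(scores, labels)
    pos = _positive_mask(labels)
    auc_value = roc_auc(scores, labels).auc if 0 < pos.sum() < len(pos) else None
    return metrics(cm, auc_value)


# ---------------------------------------------------------------- DeLong test


def _midrank(x: np.ndarray) -> np.ndarray:
    """Midranks (average ranks for ties), 1-based."""
    return stats.rankdata(x, method="average")


def _delong_components(scores: np.ndarray, pos: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC and its structural components V10 (per positive), V01 (per negative)."""
    xs = scores[pos]
    ys = scores[~pos]
    m, n = len(xs), len(ys)
    tz = _midrank(np.concatenate([xs, ys]))
    tx = _midrank(xs)
    ty = _midrank(ys)
    auc_value = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (tz[:m] - tx) / n
    v01 = 1.0 - (tz[m:] - ty) / m
    return float(auc_value), v10, v01


def compare_roc(
    scores_a,
    scores_b,
    labels,
    labels_b=None,
    paired: bool = True,
) -> tuple[float, float]:
    """DeLong test for the difference between two AUCs.

    Paired: both score lists refer to the same cases (``labels``). Unpaired:
    ``labels_b`` gives the second cohort's labels and the variances add.
    Returns ``(chi2_statistic, p_value)`` with the statistic z² on 1 df.
    Degenerate variance yields p = 1 with a warning.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    pos_a = _positive_mask(labels)
    if pos_a.all() or (~pos_a).all():
        raise ValueError("compare_roc needs both classes present")
    auc_a, v10_a, v01_a = _delong_components(scores_a, pos_a)

    if paired:
        if labels_b is not None:
            raise ValueError("paired comparison uses a single label vector")
        if len(scores_b) != len(scores_a):
            raise ValueError("paired comparison requires the same cases in both score lists")
        auc_b, v10_b, v01_b = _delong_components(scores_b, pos_a)
        m, n = len(v10_a), len(v01_a)
        s10 = np.cov(np.stack([v10_a, v10_b]), ddof=1)
        s01 = np.cov(np.stack([v01_a, v01_b]), ddof=1)
        var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
            s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
        ) / n
    else:
        if labels_b is None:
            raise ValueError("unpaired comparison requires labels_b")
        pos_b = _positive_mask(labels_b)
        if pos_b.all() or (~pos_b).all():
            raise ValueError("compare_roc needs both classes present in cohort B")
        auc_b, v10_b, v01_b = _delong_components(scores_b, pos_b)
        var = (
            np.var(v10_a, ddof=1) / len(v10_a)
            + np.var(v01_a, ddof=1) / len(v01_a)
            + np.var(v10_b, ddof=1) / len(v10_b)
            + np.var(v01_b, ddof=1) / len(v01_b)
        )

    delta = auc_a - auc_b
    if var <= 0 or not np.isfinite(var):
        if delta == 0:
            return 0.0, 1.0
        warnings.warn("compare_roc: degenerate variance, returning p = 1", stacklevel=2)
        return 0.0, 1.0
    z = delta / np.sqrt(var)
    chi2 = float(z * z)
    p = float(stats.chi2.sf(chi2, df=1))
    return chi2, p
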