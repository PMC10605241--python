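"""The 15-feature interpretable threshold rule set for GBM vs normal tissue.

Twelve GLCM features and three GLRLM features separate the two classes with
simple one-dimensional cutoffs: GBM tissue runs higher in contrast,
difference variance, the entropy family, dissimilarity, gray-level
non-uniformity and the low-gray-level run emphases, and lower in energy,
maximum probability, the homogeneity pair and the normalized inverse
differences. Where the two classes were reported with a gap between their
ranges, the rule keeps both printed bounds and decides at the midpoint.

A value exactly at the decision cutoff votes GBM — consistent with the >= 0.5
model-score convention and conservative in a screening setting.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .features import FEATURE_NAMES

__all__ = [
    "ThresholdRule",
    "builtin_rules",
    "classify_by_rules",
    "separation_report",
    "ThresholdRuleClassifier",
    "rules_to_csv",
    "rules_from_csv",
]

GBM_SIDES = ("above", "below")


@dataclass(frozen=True)
class ThresholdRule:
    """One feature cutoff. ``cutoff_low``/``cutoff_high`` are the printed class
    bounds (``cutoff_high`` absent when a single number splits both classes);
    the decision cutoff is their midpoint when both are present."""

    feature: str
    cutoff_low: float
    cutoff_high: float | None
    gbm_side: str
    source: str = ""

    def __post_init__(self) -> None:
        if self.feature not in FEATURE_NAMES:
            raise ValueError(f"unknown feature {self.feature!r}")
        if self.gbm_side not in GBM_SIDES:
            raise ValueError(f"gbm_side must be one of {GBM_SIDES}")
        if self.cutoff_high is not None and not self.cutoff_high > self.cutoff_low:
            raise ValueError("cutoff_high must exceed cutoff_low")

    @property
    def cutoff(self) -> float:
        """The decision cutoff used for voting."""
        if self.cutoff_high is None:
            return self.cutoff_low
        return (self.cutoff_low + self.cutoff_high) / 2.0

    def vote(self, value: float) -> str:
        """Class this rule votes for; a value at the cutoff votes GBM."""
        if self.gbm_side == "above":
            return "GBM" if value >= self.cutoff else "NORMAL"
        return "GBM" if value <= self.cutoff else "NORMAL"


def builtin_rules() -> list[ThresholdRule]:
    """The published rule set: 12 GLCM + 3 GLRLM cutoffs.

    The difference-variance cutoff was reported only as behaving like
    contrast; its default of 0.4 mirrors the contrast boundary of the normal
    group and is configurable by editing the returned list.
    """
    r = ThresholdRule
    return [
        r("contrast", 0.4, 0.5, "above", "normal < 0.4; GBM 0.5-3.5"),
        r("difference_variance", 0.4, None, "above", "reported as behaving like contrast"),
        r("entropy", 1.52, 1.6, "above", "normal < 1.52; GBM > 1.6"),
        r("sum_entropy", 1.3, 1.5, "above", "normal < 1.3; GBM > 1.5"),
        r("difference_entropy", 0.6, 0.8, "above", "normal < 0.6; GBM > 0.8"),
        r("dissimilarity", 0.3, None, "above", "normal < 0.3; GBM > 0.3"),
        r("energy", 0.28, None, "below", "normal > 0.28; GBM < 0.28"),
        r("maximum_probability", 0.43, 0.5, "below", "GBM < 0.43; normal > 0.5"),
        r("homogeneity1", 0.85, None, "below", "normal > 0.85; GBM < 0.85"),
        r("homogeneity2", 0.85, None, "below", "normal > 0.85; GBM < 0.85"),
        r("idn", 0.97, None, "below", "normal > 0.97; GBM < 0.97"),
        r("idmn", 0.995, None, "below", "cutoff 0.995; GBM below"),
        r("gln", 1e5, None, "above", "normal < 1e5; GBM > 1e5"),
        r("lgre", 0.3, 0.49, "above", "normal < 0.3; GBM > 0.49"),
        r("lrlge", 5.1, 5.2, "above", "normal < 5.1; GBM 5.2-35"),
    ]


def classify_by_rules(
    fv: pd.Series | dict, rules: list[ThresholdRule] | None = None
) -> tuple[int, int, str]:
    """Majority vote of the rules on one feature vector; ties go to GBM."""
    rules = builtin_rules() if rules is None else rules
    votes_gbm = votes_normal = 0
    for rule in rules:
        if rule.feature not in fv:
            raise KeyError(f"feature vector is missing {rule.feature!r}")
        value = float(fv[rule.feature])
        if np.isnan(value):
            raise ValueError(f"feature {rule.feature!r} is NaN")
        if rule.vote(value) == "GBM":
            votes_gbm += 1
        else:
            votes_normal += 1
    verdict = "GBM" if votes_gbm >= votes_normal else "NORMAL"
    return votes_gbm, votes_normal, verdict


def separation_report(
    table: pd.DataFrame, rules: list[ThresholdRule] | None = None
) -> pd.DataFrame:
    """Per-rule class separation on a labeled feature table.

    For each rule: the fraction of GBM images on the rule's GBM side, the
    fraction of normal images on the opposite side, and their mean
    (concordance, 1.0 = perfect separation, ~0.5 = chance).
    """
    rules = builtin_rules() if rules is None else rules
    labels = table["label"].astype(str)
    gbm = table[labels == "GBM"]
    normal = table[labels == "NORMAL"]
    if len(gbm) == 0 or len(normal) == 0:
        raise ValueError("separation_report needs at least one image per class")
    rows = []
    for rule in rules:
        gbm_votes = np.array([rule.vote(v) for v in gbm[rule.feature].astype(float)])
        nrm_votes = np.array([rule.vote(v) for v in normal[rule.feature].astype(float)])
        frac_gbm = float((gbm_votes == "GBM").mean())
        frac_normal = float((nrm_votes == "NORMAL").mean())
        rows.append(
            {
                "feature": rule.feature,
                "cutoff": rule.cutoff,
                "gbm_side": rule.gbm_side,
                "frac_gbm_correct": frac_gbm,
                "frac_normal_correct": frac_normal,
                "concordance": (frac_gbm + frac_normal) / 2.0,
            }
        )
    return pd.DataFrame(rows)


class ThresholdRuleClassifier(ClassifierMixin, BaseEstimator):
    """Majority-vote rule classifier over the 33-feature table.

    ``fit`` only records the feature layout (the cutoffs are fixed published
    constants, not estimated); it accepts a DataFrame with the canonical
    feature columns or a bare (n, 33) array in canonical column order.
    """

    def __init__(self, rules: list[ThresholdRule] | None = None) -> None:
        self.rules = rules

    def _resolve_rules(self) -> list[ThresholdRule]:
        return builtin_rules() if self.rules is None else list(self.rules)

    def _as_frame(self, X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return X
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(FEATURE_NAMES):
            raise ValueError(f"expected (n, {len(FEATURE_NAMES)}) array or a feature DataFrame")
        return pd.DataFrame(X, columns=FEATURE_NAMES)

    def fit(self, X, y=None) -> "ThresholdRuleClassifier":
        frame = self._as_frame(X)
        rules = self._resolve_rules()
        missing = [r.feature for r in rules if r.feature not in frame.columns]
        if missing:
            raise ValueError(f"feature table missing columns: {missing}")
        self.rules_ = rules
        self.classes_ = np.array(["GBM", "NORMAL"])
        return self

    def decision_function(self, X) -> np.ndarray:
        """Fraction of rules voting GBM, in [0, 1]."""
        check_is_fitted(self, "rules_")
        frame = self._as_frame(X)
        out = np.empty(len(frame))
        for k, (_, row) in enumerate(frame.iterrows()):
            votes_gbm, votes_normal, _ = classify_by_rules(row, self.rules_)
            out[k] = votes_gbm / (votes_gbm + votes_normal)
        return out

    def predict(self, X) -> np.ndarray:
        share = self.decision_function(X)
        return np.where(share >= 0.5, "GBM", "NORMAL")


def rules_to_csv(rules: list[ThresholdRule], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "feature": r.feature,
                "cutoff_low": r.cutoff_low,
                "cutoff_high": "" if r.cutoff_high is None else r.cutoff_high,
                "gbm_side": r.gbm_side,
                "source": r.source,
            }
            for r in rules
        ]
    ).to_csv(path, index=False)


def rules_from_csv(path: str | Path) -> list[ThresholdRule]:
    frame = pd.read_csv(path, keep_default_na=False)
    out = []
    for _, row in frame.iterrows():
        high = row["cutoff_high"]
        high = None if high in ("", None) else float(high)
        out.append(
            ThresholdRule(
                str(row["feature"]),
                float(row["cutoff_low"]),
                high,
                str(row["gbm_side"]),
                str(row.get("source", "")),
            )
        )
    return out
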