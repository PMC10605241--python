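"""Model building: stratified 70/15/15 splits, five classifier families, 10-fold CV.

The five families mirror the usual off-the-shelf choices for tabular texture
features: a CART decision tree (DT), gradient-boosted trees (EB), a
500-tree random forest (RF), an RBF-kernel SVM on standardized features
(SVM), and logistic regression (LM) as the linear model. Every model emits a
score in [0, 1] for the positive class (GBM); the decision threshold is 0.5
with values exactly at 0.5 classified as GBM.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted

from .features import FEATURE_NAMES

__all__ = [
    "ALGORITHMS",
    "SplitPlan",
    "split_dataset",
    "TextureClassifier",
    "train",
    "predict_score",
    "classify_score",
    "cross_validate_10fold",
]

ALGORITHMS = ("dt", "eb", "rf", "svm", "lm")

POSITIVE = "GBM"
NEGATIVE = "NORMAL"
SCORE_THRESHOLD = 0.5


@dataclass
class SplitPlan:
    """Disjoint train/validation/test row indices of a feature table."""

    train: np.ndarray
    validation: np.ndarray
    test: np.ndarray
    seed: int
    stratified: bool = True
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)

    def __post_init__(self) -> None:
        sets = [set(self.train), set(self.validation), set(self.test)]
        n = sum(len(s) for s in sets)
        if len(sets[0] | sets[1] | sets[2]) != n:
            raise ValueError("split sets must be disjoint")


def split_dataset(
    labels: pd.Series | np.ndarray,
    seed: int,
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
    stratified: bool = True,
    groups: np.ndarray | None = None,
) -> SplitPlan:
    """Stratified 70/15/15 split of row indices, deterministic per seed.

    Validation and test sizes are floored per class; the remainder goes to
    training. With ``groups`` (e.g. patient ids) whole groups are assigned to
    one partition, preventing images of one patient leaking across splits.
    """
    labels = np.asarray(labels)
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    tr, va, te = [], [], []

    def allot(idx: np.ndarray) -> None:
        n = len(idx)
        n_va = int(np.floor(fractions[1] * n))
        n_te = int(np.floor(fractions[2] * n))
        perm = rng.permutation(idx)
        va.extend(perm[:n_va])
        te.extend(perm[n_va : n_va + n_te])
        tr.extend(perm[n_va + n_te :])

    strata = np.unique(labels) if stratified else np.array([None])
    for cls in strata:
        sel = np.arange(len(labels)) if cls is None else np.flatnonzero(labels == cls)
        if stratified and len(sel) < 3:
            raise ValueError(f"class {cls!r} has fewer than 3 rows")
        if groups is None:
            allot(sel)
        else:
            # group-wise allotment within the stratum, by unique group id
            g = np.asarray(groups)[sel]
            uniq = np.unique(g)
            n_va = int(np.floor(fractions[1] * len(uniq)))
            n_te = int(np.floor(fractions[2] * len(uniq)))
            perm = rng.permutation(uniq)
            va_g, te_g = set(perm[:n_va]), set(perm[n_va : n_va + n_te])
            for i, gi in zip(sel, g):
                (va if gi in va_g else te if gi in te_g else tr).append(i)
    return SplitPlan(np.sort(tr), np.sort(va), np.sort(te), seed, stratified, tuple(fractions))


def _base_estimator(algorithm: str, random_state: int, params: dict) -> BaseEstimator:
    if algorithm == "dt":
        return DecisionTreeClassifier(random_state=random_state, **params)
    if algorithm == "eb":
        return GradientBoostingClassifier(random_state=random_state, **params)
    if algorithm == "rf":
        params = {"n_estimators": 500, **params}
        return RandomForestClassifier(random_state=random_state, **params)
    if algorithm == "svm":
        return make_pipeline(StandardScaler(), SVC(kernel="rbf", random_state=random_state, **params))
    if algorithm == "lm":
        return make_pipeline(
            StandardScaler(), LogisticRegression(max_iter=1000, random_state=random_state, **params)
        )
    raise ValueError(f"algorithm must be one of {ALGORITHMS}, got {algorithm!r}")


@dataclass
class ModelSpec:
    """Algorithm choice plus hyperparameter overrides and the training seed."""

    algorithm: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"algorithm must be one of {ALGORITHMS}")


class TextureClassifier(ClassifierMixin, BaseEstimator):
    """One of the five classifier families with a common [0, 1] scoring surface.

    ``predict_score`` returns a probability-like score for GBM: tree vote
    fractions (DT/RF), the boosted ensemble's logistic output (EB), the SVM
    decision distance squashed through a logistic, and the logistic-regression
    probability (LM). ``predict`` applies the 0.5 threshold with ties -> GBM.
    """

    def __init__(
        self, algorithm: str = "svm", random_state: int = 0, hyperparameters: dict | None = None
    ) -> None:
        self.algorithm = algorithm
        self.random_state = random_state
        self.hyperparameters = hyperparameters

    def fit(self, X, y) -> "TextureClassifier":
        X, y = self._check_Xy(X, y)
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValueError("training data must contain both classes")
        est = _base_estimator(self.algorithm, self.random_state, dict(self.hyperparameters or {}))
        self.estimator_ = est.fit(X, y)
        self.classes_ = np.array([POSITIVE, NEGATIVE]) if set(classes) == {POSITIVE, NEGATIVE} else classes
        self.n_features_in_ = X.shape[1]
        return self

    def _check_Xy(self, X, y=None):
        if isinstance(X, pd.DataFrame):
            cols = [c for c in FEATURE_NAMES if c in X.columns]
            X = X[cols].to_numpy(dtype=float) if cols else X.to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
        if np.isnan(X).any():
            raise ValueError("feature matrix contains NaN")
        if y is None:
            return X
        return X, np.asarray(y).astype(str)

    def predict_score(self, X) -> np.ndarray:
        """Score in [0, 1]; larger means more GBM-like."""
        check_is_fitted(self, "estimator_")
        X = self._check_Xy(X)
        est = self.estimator_
        if self.algorithm == "svm":
            # distance to the separating surface, monotonely squashed into [0,1]
            d = est.decision_function(X)
            inner = est[-1]
            if list(inner.classes_).index(POSITIVE) == 0:
                d = -d
            score = expit(d)
        else:
            proba = est.predict_proba(X)
            score = proba[:, list(est.classes_).index(POSITIVE)]
        return np.clip(score, 0.0, 1.0)

    def predict(self, X) -> np.ndarray:
        return np.where(self.predict_score(X) >= SCORE_THRESHOLD, POSITIVE, NEGATIVE)


#: Small per-algorithm grids searched on the validation split when tuning.
_VALIDATION_GRIDS = {
    "dt": [{"max_depth": d} for d in (None, 5, 10)],
    "eb": [{"n_estimators": n} for n in (100, 300)],
    "rf": [{"n_estimators": n} for n in (300, 500)],
    "svm": [{"C": c} for c in (0.1, 1.0, 10.0)],
    "lm": [{"C": c} for c in (0.1, 1.0, 10.0)],
}


def train(
    spec: ModelSpec | str,
    train_table: pd.DataFrame,
    validation_table: pd.DataFrame | None = None,
    seed: int | None = None,
    tune: bool = False,
) -> TextureClassifier:
    """Fit one classifier family on a labeled feature table.

    The validation table is used only for hyperparameter selection when
    ``tune=True``; otherwise the family's defaults are used and the
    validation split remains an untouched sanity check.
    """
    if isinstance(spec, str):
        spec = ModelSpec(spec, seed=seed if seed is not None else 0)
    if seed is not None:
        spec = ModelSpec(spec.algorithm, dict(spec.hyperparameters), seed)
    y = train_table["label"].astype(str).to_numpy()
    if len(train_table) == 0 or len(np.unique(y)) < 2:
        raise ValueError("training table must be nonempty with both classes")
    best_params = dict(spec.hyperparameters)
    if tune:
        if validation_table is None or len(validation_table) == 0:
            raise ValueError("tune=True requires a nonempty validation table")
        y_val = validation_table["label"].astype(str).to_numpy()
        best_acc = -1.0
        for params in _VALIDATION_GRIDS[spec.algorithm]:
            clf = TextureClassifier(spec.algorithm, spec.seed, {**spec.hyperparameters, **params})
            clf.fit(train_table, y)
            acc = float((clf.predict(validation_table) == y_val).mean())
            if acc > best_acc:
                best_acc, best_params = acc, {**spec.hyperparameters, **params}
    model = TextureClassifier(spec.algorithm, spec.seed, best_params)
    return model.fit(train_table, y)


def predict_score(model: TextureClassifier, fv) -> np.ndarray:
    """Thin wrapper: score feature vectors with a trained model."""
    if isinstance(fv, (pd.Series, dict)):
        fv = pd.DataFrame([fv])
    return model.predict_score(fv)


def classify_score(score: float) -> str:
    """Apply the 0.5 decision threshold; a score of exactly 0.5 is GBM."""
    if not 0.0 <= score <= 1.0:
        raise ValueError("score must lie in [0, 1]")
    return POSITIVE if score >= SCORE_THRESHOLD else NEGATIVE


def cross_validate_10fold(
    spec: ModelSpec | str,
    table: pd.DataFrame,
    seed: int = 0,
    n_folds: int = 10,
) -> pd.DataFrame:
    """Stratified k-fold cross-validation (default 10 folds of equal size ±1).

    Returns one row per fold plus a final "mean" row, with accuracy,
    sensitivity, specificity and AUC computed on each held-out fold.
    """
    from .evaluate import evaluate_scores  # local import to avoid a cycle

    if isinstance(spec, str):
        spec = ModelSpec(spec, seed=seed)
    y = table["label"].astype(str).to_numpy()
    counts = pd.Series(y).value_counts()
    if (counts < n_folds).any():
        raise ValueError(f"each class needs at least {n_folds} rows")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    rows = []
    X_index = np.arange(len(table))
    for fold, (tr, te) in enumerate(skf.split(X_index, y), start=1):
        model = TextureClassifier(spec.algorithm, spec.seed, dict(spec.hyperparameters))
        model.fit(table.iloc[tr], y[tr])
        scores = model.predict_score(table.iloc[te])
        rep = evaluate_scores(scores, y[te])
        rows.append(
            {
                "fold": fold,
                "n_test": len(te),
                "accuracy": rep.accuracy,
                "sensitivity": rep.sensitivity,
                "specificity": rep.specificity,
                "auc": rep.auc,
            }
        )
    out = pd.DataFrame(rows)
    mean_row = out.drop(columns="fold").mean().to_dict()
    out = pd.concat([out, pd.DataFrame([{"fold": "mean", **mean_row}])], ignore_index=True)
    return out
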