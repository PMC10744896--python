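"""Classifier training and repeated stratified nested cross-validation.

The evaluation protocol: an outer stratified k-fold loop estimates
generalization; inside each outer training fold an inner stratified k-fold
grid search picks hyperparameters by AUROC; the winner is refit on the whole
outer training fold and scored once on the held-out outer fold.  The whole
loop is repeated with different shuffles and metrics are averaged over folds,
then over repeats.  Feature selection, when per-fold, runs strictly inside
the outer training fold.

Model families mirror a standard tabular-clinical toolbox: random forest,
gradient-boosted trees, logistic regression, and three ensemble wrappers with
random-forest base learners (bagging, AdaBoost, gradient boosting).  The
final model of interest is bagging over random forests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import (
    AdaBoostClassifier,
    BaggingClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.inspection import permutation_importance
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

MODEL_FAMILIES = (
    "random_forest",
    "gradient_boosted_trees",
    "logistic_regression",
    "bagging_rf",
    "adaboost_rf",
    "gradboost",
)

METRIC_NAMES = ("accuracy", "precision", "recall", "specificity", "f1", "auroc")

#: default hyperparameter grid for the random-forest family
RF_GRID = {"n_estimators": [50, 100, 200], "max_features": ["sqrt", "log2"]}


@dataclass
class ModelSpec:
    """A model family plus fixed hyperparameters and an optional search grid."""

    family: str = "random_forest"
    params: dict = field(default_factory=dict)
    grid: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in MODEL_FAMILIES:
            raise ValueError(
                f"unknown model family {self.family!r}; choose from {MODEL_FAMILIES}"
            )


def _base_rf(seed: int, **overrides) -> RandomForestClassifier:
    kw = dict(n_estimators=100, max_features="log2", random_state=seed)
    kw.update(overrides)
    return RandomForestClassifier(**kw)


def build_estimator(spec: ModelSpec, seed: int = 0):
    """Instantiate the sklearn estimator for a :class:`ModelSpec`."""
    p = dict(spec.params)
    if spec.family == "random_forest":
        return _base_rf(seed, **p)
    if spec.family == "logistic_regression":
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("clf", LogisticRegression(max_iter=2000, random_state=seed, **p)),
            ]
        )
    if spec.family == "bagging_rf":
        kw = dict(
            n_estimators=50,
            bootstrap=True,
            bootstrap_features=True,
            max_features=0.5,
            max_samples=0.5,
        )
        kw.update(p)
        return BaggingClassifier(
            estimator=_base_rf(seed), random_state=seed, **kw
        )
    if spec.family == "adaboost_rf":
        kw = dict(n_estimators=50)
        kw.update(p)
        return AdaBoostClassifier(estimator=_base_rf(seed), random_state=seed, **kw)
    if spec.family == "gradboost":
        return GradientBoostingClassifier(random_state=seed, **p)
    if spec.family == "gradient_boosted_trees":
        try:
            from xgboost import XGBClassifier

            kw = dict(n_estimators=100, eval_metric="logloss", verbosity=0)
            kw.update(p)
            return XGBClassifier(random_state=seed, **kw)
        except ImportError:
            return GradientBoostingClassifier(random_state=seed, **p)
    raise AssertionError(spec.family)


def _as_binary(y) -> np.ndarray:
    y = np.asarray(y)
    if y.dtype.kind in "OUS":
        return (y == "case").astype(int)
    return y.astype(int)


def compute_metrics(y_true, y_score, threshold: float = 0.5) -> dict[str, float]:
    """Confusion-matrix metrics at a score threshold, plus AUROC.

    AUROC follows the rank definition (probability a random case outscores a
    random control, ties counting one half), which the trapezoidal ROC area
    realizes.  Degenerate denominators (no predicted positives, etc.) yield 0
    for the affected ratio rather than NaN.
    """
    yt = _as_binary(y_true)
    ys = np.asarray(y_score, dtype=float)
    if len(np.unique(yt)) < 2:
        raise ValueError("AUROC undefined: y_true contains a single class")
    yp = (ys >= threshold).astype(int)
    tp = int(np.sum((yt == 1) & (yp == 1)))
    fp = int(np.sum((yt == 0) & (yp == 1)))
    tn = int(np.sum((yt == 0) & (yp == 0)))
    fn = int(np.sum((yt == 1) & (yp == 0)))

    def ratio(num: float, den: float) -> float:
        return num / den if den else 0.0

    precision = ratio(tp, tp + fp)
    recall = ratio(tp, tp + fn)
    return {
        "tp": tp,
        "fp": fp,
        "tn": tn,
        "fn": fn,
        "accuracy": (tp + tn) / len(yt),
        "precision": precision,
        "recall": recall,
        "specificity": ratio(tn, tn + fp),
        "f1": ratio(2 * precision * recall, precision + recall),
        "auroc": float(roc_auc_score(yt, ys)),
    }


@dataclass
class EvalResult:
    """Per-repeat/per-fold metrics of a nested cross-validation run."""

    folds: pd.DataFrame  # columns: repeat, fold, tp..fn, metrics

    def by_repeat(self) -> pd.DataFrame:
        return self.folds.groupby("repeat")[list(METRIC_NAMES)].mean()

    @property
    def mean(self) -> dict[str, float]:
        return self.by_repeat().mean().to_dict()

    def to_dict(self) -> dict:
        return {
            "mean": self.mean,
            "by_repeat": self.by_repeat().round(6).to_dict(orient="index"),
            "folds": self.folds.round(6).to_dict(orient="records"),
        }


def nested_cv(
    X: pd.DataFrame,
    y,
    spec: ModelSpec,
    outer: int = 5,
    inner: int = 5,
    repeats: int = 5,
    seed: int = 0,
    selector: Callable[[pd.DataFrame, np.ndarray], Sequence[str]] | None = None,
) -> EvalResult:
    """Repeated stratified nested cross-validation.

    ``selector``, when given, is called with the outer *training* fold only
    and returns the feature names to train on — the hook for per-fold feature
    selection without test-fold leakage.  Repeat r uses shuffle seed
    ``seed + r`` end to end, so a run is reproducible from ``seed`` alone.
    """
    yb = _as_binary(y)
    counts = np.bincount(yb, minlength=2)
    if counts.min() < outer:
        raise ValueError(
            f"stratified {outer}-fold CV impossible: class counts {counts.tolist()}"
        )
    rows = []
    for r in range(repeats):
        rs = seed + r
        outer_cv = StratifiedKFold(outer, shuffle=True, random_state=rs)
        for fold, (tr, te) in enumerate(outer_cv.split(X, yb)):
            X_tr, y_tr = X.iloc[tr], yb[tr]
            feats = list(selector(X_tr, y_tr)) if selector is not None else list(X.columns)
            if not feats:  # selector found nothing; fall back to all features
                feats = list(X.columns)
            est = build_estimator(spec, seed=rs)
            if spec.grid:
                search = GridSearchCV(
                    est,
                    spec.grid,
                    scoring="roc_auc",
                    cv=StratifiedKFold(inner, shuffle=True, random_state=rs),
                    n_jobs=None,
                )
                search.fit(X_tr[feats], y_tr)
                model = search.best_estimator_
            else:
                model = est.fit(X_tr[feats], y_tr)
            scores = model.predict_proba(X.iloc[te][feats])[:, 1]
            m = compute_metrics(yb[te], scores)
            rows.append({"repeat": r, "fold": fold, "n_test": len(te), **m})
    return EvalResult(folds=pd.DataFrame(rows))


def train_final(
    X: pd.DataFrame,
    y,
    spec: ModelSpec | None = None,
    seed: int = 0,
    holdout: float = 0.25,
    n_importance_repeats: int = 10,
):
    """Fit the final ensemble and rank features by permutation importance.

    Importance is measured on a stratified holdout split: each feature column
    is shuffled and the drop in holdout AUROC recorded, averaged over
    ``n_importance_repeats`` shuffles.  Returns ``(model, importances,
    holdout_metrics)`` with importances as a descending-sorted DataFrame.
    """
    if spec is None:
        spec = ModelSpec(family="bagging_rf")
    yb = _as_binary(y)
    if len(yb) < 10:
        raise ValueError(f"refusing to fit the final model on n={len(yb)} (< 10)")
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, yb, test_size=holdout, stratify=yb, random_state=seed
    )
    model = build_estimator(spec, seed=seed).fit(X_tr, y_tr)
    imp = permutation_importance(
        model,
        X_te,
        y_te,
        scoring="roc_auc",
        n_repeats=n_importance_repeats,
        random_state=seed,
    )
    importances = (
        pd.DataFrame(
            {
                "feature": X.columns,
                "importance": imp.importances_mean,
                "importance_sd": imp.importances_std,
            }
        )
        .sort_values("importance", ascending=False, kind="stable")
        .reset_index(drop=True)
    )
    metrics = compute_metrics(y_te, model.predict_proba(X_te)[:, 1])
    return model, importances, metrics
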