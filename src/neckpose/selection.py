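"""Dual feature selection: Mann-Whitney U screening and L1-logistic weights.

The two selectors answer different questions — marginal case/control
separation per feature versus joint sparse predictive weight — and the
pipeline trains on their *union*.  No multiple-testing correction is applied
to the U-test screen; the alpha = 0.01 cut is a screening rule, not an
inference, and downstream nested cross-validation carries the error control.

Selection can run once on the full cohort (``global`` scope) or inside each
outer training fold of the nested CV (``per_fold``).  Global selection leaks
test-fold information into the feature set and optimistically biases the
evaluation; per-fold is the honest default for benchmarking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler


@dataclass
class SelectionResult:
    """Outcome of dual selection on one training set."""

    utest_pvalues: dict[str, float]  # selected features only
    lasso_weights: dict[str, float]  # nonzero-coefficient features only
    schema: list[str] = field(default_factory=list)  # canonical ordering

    def _ordered(self, names: set[str]) -> list[str]:
        order = self.schema or sorted(names)
        return [n for n in order if n in names]

    @property
    def utest_selected(self) -> list[str]:
        return self._ordered(set(self.utest_pvalues))

    @property
    def lasso_selected(self) -> list[str]:
        return self._ordered(set(self.lasso_weights))

    @property
    def intersection(self) -> list[str]:
        return self._ordered(set(self.utest_pvalues) & set(self.lasso_weights))

    @property
    def union(self) -> list[str]:
        return self._ordered(set(self.utest_pvalues) | set(self.lasso_weights))

    def to_dict(self) -> dict:
        return {
            "utest": {n: self.utest_pvalues[n] for n in self.utest_selected},
            "lasso": {n: self.lasso_weights[n] for n in self.lasso_selected},
            "intersection": self.intersection,
            "union": self.union,
        }


def _as_binary(y) -> np.ndarray:
    y = np.asarray(y)
    if y.dtype.kind in "OUS":
        return (y == "case").astype(int)
    return y.astype(int)


def utest_select(
    X: pd.DataFrame, y, alpha: float = 0.01
) -> tuple[list[str], dict[str, float]]:
    """Two-sided Mann-Whitney U per feature; keep p < alpha.

    Uses the exact null distribution for small untied samples and the
    tie-corrected normal approximation otherwise (scipy's automatic choice).
    Features constant across all subjects carry no ordering information and
    are skipped with a warning.
    """
    yb = _as_binary(y)
    if min(yb.sum(), (1 - yb).sum()) < 2:
        raise ValueError("need at least 2 subjects per class for the U-test")
    if X.isna().any().any():
        raise ValueError("feature matrix contains missing values")
    pvals: dict[str, float] = {}
    skipped = []
    case = X[yb == 1]
    ctrl = X[yb == 0]
    for name in X.columns:
        col = X[name].to_numpy(dtype=float)
        if np.ptp(col) == 0:
            skipped.append(name)
            continue
        res = stats.mannwhitneyu(
            case[name], ctrl[name], alternative="two-sided", method="auto"
        )
        pvals[name] = float(res.pvalue)
    if skipped:
        warnings.warn(
            f"{len(skipped)} constant features skipped by the U-test screen",
            stacklevel=2,
        )
    selected = [n for n in X.columns if pvals.get(n, 1.0) < alpha]
    return selected, {n: pvals[n] for n in selected}


def lasso_select(
    X: pd.DataFrame, y, seed: int = 0, n_folds: int = 5
) -> tuple[list[str], dict[str, float]]:
    """L1-penalized logistic regression; selected = nonzero coefficients.

    Features are standardized internally; the penalty strength is chosen by
    stratified cross-validated AUROC over a log-spaced grid.  Weights are
    reported on the standardized scale.
    """
    yb = _as_binary(y)
    n_folds = min(n_folds, int(yb.sum()), int((1 - yb).sum()))
    if n_folds < 2:
        raise ValueError("need at least 2 subjects per class for Lasso selection")
    model = make_pipeline(
        StandardScaler(),
        LogisticRegressionCV(
            penalty="l1",
            solver="liblinear",
            Cs=np.logspace(-2, 1, 8),
            cv=StratifiedKFold(n_folds, shuffle=True, random_state=seed),
            scoring="roc_auc",
            max_iter=2000,
            random_state=seed,
        ),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(X.to_numpy(dtype=float), yb)
    coefs = model.named_steps["logisticregressioncv"].coef_.ravel()
    weights = {
        name: float(c) for name, c in zip(X.columns, coefs) if c != 0.0
    }
    if not weights:
        warnings.warn("Lasso selected no features at any penalty", stacklevel=2)
    selected = [n for n in X.columns if n in weights]
    return selected, weights


def combine(
    utest_pvalues: dict[str, float],
    lasso_weights: dict[str, float],
    schema: list[str] | None = None,
) -> SelectionResult:
    """Set algebra over the two selected sets with a deterministic ordering."""
    return SelectionResult(
        utest_pvalues=dict(utest_pvalues),
        lasso_weights=dict(lasso_weights),
        schema=list(schema) if schema is not None else [],
    )


def select_features(
    X: pd.DataFrame, y, alpha: float = 0.01, seed: int = 0
) -> SelectionResult:
    """Run both selectors on one training set and combine them."""
    _, pvals = utest_select(X, y, alpha=alpha)
    _, weights = lasso_select(X, y, seed=seed)
    return combine(pvals, weights, schema=list(X.columns))
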