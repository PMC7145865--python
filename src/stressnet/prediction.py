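"""Cross-validated linear SVR prediction of a behavioral score.

The prediction statistic is ``r(predicted, observed)``: the Pearson
correlation between pooled out-of-fold predictions and the observed
outcomes.  Folds are outcome-balanced — subjects are sorted by the outcome,
cut into consecutive groups of ``k``, and each group is dealt round-robin
into the ``k`` folds (group order randomized by the seed) so every fold
sees the full outcome distribution.  The regressor is an
epsilon-insensitive linear SVR; features are standardized with
training-fold statistics only, and an optional covariate set is regressed
out of the outcome using coefficients fitted on the training folds only, so
no information leaks into the held-out fold.  Significance is assessed by a
permutation test on the outcome.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.model_selection import BaseCrossValidator
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVR


class BalancedKFold(BaseCrossValidator):
    """K-fold splitter balancing the outcome distribution across folds.

    Subjects are sorted by ``y``; consecutive groups of ``n_splits`` are
    dealt round-robin into folds, with the within-group order shuffled by
    ``random_state``.  Fold sizes differ by at most one and per-fold outcome
    means are closer to the grand mean than under random assignment.
    """

    def __init__(self, n_splits: int = 4, random_state: int = 0):
        self.n_splits = n_splits
        self.random_state = random_state

    def get_n_splits(self, X=None, y=None, groups=None) -> int:
        return self.n_splits

    def fold_assignment(self, y: np.ndarray) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        n, k = y.size, self.n_splits
        if k < 2:
            raise ValueError("need at least 2 folds")
        if n < 2 * k:
            raise ValueError(f"need n >= 2k subjects (n={n}, k={k})")
        rng = np.random.default_rng(self.random_state)
        order = np.argsort(y, kind="stable")
        folds = np.empty(n, dtype=int)
        fold_perm = rng.permutation(k)  # balances remainder-group fold sizes
        for start in range(0, n, k):
            group = order[start : start + k]
            slots = rng.permutation(len(group))
            folds[group] = fold_perm[slots]
        return folds

    def _iter_test_indices(self, X=None, y=None, groups=None) -> Iterator[np.ndarray]:
        if y is None:
            raise ValueError("BalancedKFold requires y to balance folds on")
        folds = self.fold_assignment(np.asarray(y))
        for f in range(self.n_splits):
            yield np.flatnonzero(folds == f)


def balanced_folds(y: Sequence[float], k: int = 4, seed: int = 0) -> np.ndarray:
    """Fold index per subject under outcome-balanced dealing."""
    return BalancedKFold(n_splits=k, random_state=seed).fold_assignment(np.asarray(y, dtype=float))


class StandardizedLinearSVR(RegressorMixin, BaseEstimator):
    """Linear epsilon-insensitive SVR on internally standardized features."""

    def __init__(self, C: float = 1.0, epsilon: float = 0.1, max_iter: int = 20000):
        self.C = C
        self.epsilon = epsilon
        self.max_iter = max_iter

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        self.scaler_ = StandardScaler().fit(X)
        self.svr_ = LinearSVR(
            C=self.C,
            epsilon=self.epsilon,
            loss="epsilon_insensitive",
            max_iter=self.max_iter,
            tol=1e-5,
            random_state=0,
        )
        self.svr_.fit(self.scaler_.transform(X), y)
        return self

    def predict(self, X):
        return self.svr_.predict(self.scaler_.transform(np.asarray(X, dtype=float)))


@dataclass
class PredictionResult:
    """Pooled out-of-fold prediction summary."""

    r_pred_obs: float
    predictions: np.ndarray
    observed: np.ndarray
    fold_of: np.ndarray
    k: int
    C: float
    epsilon: float
    seed: int

    def to_dict(self) -> dict:
        return {
            "r_pred_obs": self.r_pred_obs,
            "k": self.k,
            "C": self.C,
            "epsilon": self.epsilon,
            "seed": self.seed,
        }


def cv_predict(
    features: np.ndarray | pd.DataFrame,
    y: Sequence[float] | np.ndarray,
    covariates: np.ndarray | None = None,
    k: int = 4,
    C: float = 1.0,
    epsilon: float = 0.1,
    seed: int = 0,
    residualize_features: bool = False,
    repeats: int = 1,
) -> PredictionResult:
    """Balanced k-fold cross-validated linear SVR prediction.

    When covariates are supplied, the outcome (and optionally each feature)
    is replaced by its residual after OLS on ``[intercept, covariates]``
    fitted on the training folds only and applied to the held-out fold.
    Every subject is predicted exactly once per repeat, by a model never
    trained on it; the final statistic is the Pearson correlation of the
    pooled out-of-fold predictions with the (residualized) observed
    outcomes.  ``repeats > 1`` reruns the whole CV with fresh fold
    assignments (seeds ``seed .. seed+repeats-1``) and reports the mean r;
    predictions and folds are those of the first repeat.
    """
    if repeats < 1:
        raise ValueError("repeats must be at least 1")
    if repeats > 1:
        runs = [
            cv_predict(
                features, y, covariates, k=k, C=C, epsilon=epsilon,
                seed=seed + i, residualize_features=residualize_features,
            )
            for i in range(repeats)
        ]
        first = runs[0]
        return PredictionResult(
            r_pred_obs=float(np.mean([r.r_pred_obs for r in runs])),
            predictions=first.predictions, observed=first.observed,
            fold_of=first.fold_of, k=k, C=C, epsilon=epsilon, seed=seed,
        )
    X = np.asarray(features, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValueError("features must be a 2-D matrix with at least one column")
    if X.shape[0] != y.size:
        raise ValueError("features and y must have one row per subject")
    if y.std() == 0:
        raise ValueError("outcome is constant; r(predicted, observed) undefined")
    cov = None
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]

    n = y.size
    folds = balanced_folds(y, k=k, seed=seed)
    preds = np.empty(n)
    obs = np.empty(n)
    for f in range(k):
        test = folds == f
        train = ~test
        y_train, y_test = y[train], y[test]
        X_train, X_test = X[train], X[test]
        if cov is not None:
            D_train = np.column_stack([np.ones(train.sum()), cov[train]])
            D_test = np.column_stack([np.ones(test.sum()), cov[test]])
            beta, *_ = np.linalg.lstsq(D_train, y_train, rcond=None)
            y_train = y_train - D_train @ beta
            y_test = y_test - D_test @ beta
            if residualize_features:
                B, *_ = np.linalg.lstsq(D_train, X_train, rcond=None)
                X_train = X_train - D_train @ B
                X_test = X_test - D_test @ B
        model = StandardizedLinearSVR(C=C, epsilon=epsilon).fit(X_train, y_train)
        preds[test] = model.predict(X_test)
        obs[test] = y_test
    r = float(np.corrcoef(preds, obs)[0, 1])
    return PredictionResult(
        r_pred_obs=r, predictions=preds, observed=obs, fold_of=folds,
        k=k, C=C, epsilon=epsilon, seed=seed,
    )


def permutation_pvalue(
    features: np.ndarray | pd.DataFrame,
    y: Sequence[float] | np.ndarray,
    covariates: np.ndarray | None = None,
    k: int = 4,
    n_perm: int = 1000,
    seed: int = 0,
    C: float = 1.0,
    epsilon: float = 0.1,
) -> tuple[float, float]:
    """Permutation p-value for ``r(predicted, observed)``.

    Permutes the outcome against the features ``n_perm`` times and reports
    ``p = (1 + #{r_perm >= r_obs}) / (1 + n_perm)`` together with the
    observed r.
    """
    if n_perm < 100:
        raise ValueError("need n_perm >= 100 for a stable permutation p-value")
    y = np.asarray(y, dtype=float)
    observed = cv_predict(features, y, covariates, k=k, C=C, epsilon=epsilon, seed=seed)
    rng = np.random.default_rng(seed)
    count = 0
    for i in range(n_perm):
        perm = rng.permutation(y.size)
        r_perm = cv_predict(
            features, y[perm],
            covariates[perm] if covariates is not None else None,
            k=k, C=C, epsilon=epsilon, seed=seed,
        ).r_pred_obs
        if r_perm >= observed.r_pred_obs:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return float(p), observed.r_pred_obs


class ConnectivityRegressor(RegressorMixin, BaseEstimator):
    """Estimator form of the balanced-fold SVR prediction analysis.

    ``fit`` runs the full cross-validation and records the pooled
    out-of-fold statistic in ``r_pred_obs_`` and per-subject predictions in
    ``oof_predictions_``, then refits a final model on all subjects for
    ``predict`` on new data.
    """

    def __init__(
        self,
        k: int = 4,
        C: float = 1.0,
        epsilon: float = 0.1,
        seed: int = 0,
        residualize_features: bool = False,
    ):
        self.k = k
        self.C = C
        self.epsilon = epsilon
        self.seed = seed
        self.residualize_features = residualize_features

    def fit(self, X, y, covariates: np.ndarray | None = None):
        result = cv_predict(
            X, y, covariates,
            k=self.k, C=self.C, epsilon=self.epsilon, seed=self.seed,
            residualize_features=self.residualize_features,
        )
        self.r_pred_obs_ = result.r_pred_obs
        self.oof_predictions_ = result.predictions
        self.oof_observed_ = result.observed
        self.fold_of_ = result.fold_of
        self.model_ = StandardizedLinearSVR(C=self.C, epsilon=self.epsilon).fit(
            np.asarray(X, dtype=float), np.asarray(y, dtype=float)
        )
        return self

    def predict(self, X):
        return self.model_.predict(X)
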