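"""Covariate-adjusted correlation screening with BH-FDR correction.

Each connectivity measure is screened against a behavioral score with a
partial Pearson correlation (both variables residualized on an intercept
plus covariates by OLS), a two-sided p-value from the t transform
``t = r * sqrt(df / (1 - r^2))`` with ``df = n - 2 - k``, and
Benjamini-Hochberg step-up correction over the whole screen family.

Two covariate presets mirror the analyses the pipeline runs: the basic
screen adjusts for age and sex; the extended preset adds current stress for
the behavior-behavior correlations.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from scipy import stats
from statsmodels.stats.multitest import multipletests

COVARIATES_BASIC: tuple[str, ...] = ("age", "sex")
COVARIATES_EXTENDED: tuple[str, ...] = ("age", "sex", "current_stress")


def _residualize(v: np.ndarray, design: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(design, v, rcond=None)
    return v - design @ beta


def partial_correlation(
    x: Sequence[float] | np.ndarray,
    y: Sequence[float] | np.ndarray,
    covariates: np.ndarray | None = None,
) -> tuple[float, float]:
    """Partial Pearson correlation of x and y given covariates.

    Residualizes both variables on ``[intercept, covariates]`` by OLS and
    correlates the residuals; with no covariates this is the plain Pearson
    correlation. Returns ``(r, p)`` with a two-sided p-value on
    ``n - 2 - k`` degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = x.size
    if covariates is None:
        cov = np.empty((n, 0))
    else:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        if cov.shape[0] != n:
            raise ValueError("covariates must have one row per observation")
    k = cov.shape[1]
    if n <= k + 3:
        raise ValueError(f"need n > k + 3 observations (n={n}, k={k})")
    design = np.column_stack([np.ones(n), cov])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("covariate matrix is rank deficient")
    rx = _residualize(x, design)
    ry = _residualize(y, design)
    sx, sy = rx.std(), ry.std()
    if sx <= 1e-10 * (x.std() + 1e-30) or sy <= 1e-10 * (y.std() + 1e-30):
        raise ValueError("degenerate partial correlation: a variable is fully explained by covariates")
    r = float(np.clip((rx * ry).mean() / (sx * sy), -1.0, 1.0))
    df = n - 2 - k
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt(df / (1.0 - r**2))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return r, p


def bh_fdr(pvalues: Sequence[float] | np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjustment.

    Returns ``(adjusted p-values, rejection flags)`` in the input order;
    adjusted ``p_(i) = min_{j >= i} min(1, m * p_(j) / j)`` and a test is
    rejected when its adjusted p-value is at most ``q``.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvalues must be a nonempty 1-D vector")
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    if not 0.0 < q < 1.0:
        raise ValueError("q must be in (0, 1)")
    reject, p_adj, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, reject


def screen(
    features: pd.DataFrame,
    behavior: pd.DataFrame,
    target: str = "els",
    covariates: Sequence[str] = COVARIATES_BASIC,
    q: float = 0.05,
    measures: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Screen every connectivity measure against a behavioral score.

    ``features`` is the subjects-by-measures profile frame (indexed by
    subject id); ``behavior`` the per-subject behavioral table.  One BH-FDR
    family covers all measures tested in the invocation.

    Returns a frame with columns ``measure, r, p, p_adj, significant``.
    """
    behavior = behavior.set_index("subject_id") if "subject_id" in behavior.columns else behavior
    unmatched = features.index.difference(behavior.index)
    if len(unmatched):
        raise ValueError(f"subjects missing from behavioral table: {list(unmatched[:5])}")
    behavior = behavior.loc[features.index]
    cov = behavior[list(covariates)].to_numpy(dtype=float) if covariates else None
    y = behavior[target].to_numpy(dtype=float)
    cols = list(measures) if measures is not None else list(features.columns)
    rows = []
    for measure in cols:
        r, p = partial_correlation(features[measure].to_numpy(dtype=float), y, cov)
        rows.append((measure, r, p))
    out = pd.DataFrame(rows, columns=["measure", "r", "p"])
    out["p_adj"], out["significant"] = bh_fdr(out["p"].to_numpy(), q)
    return out


class CorrelationScreen(BaseEstimator):
    """Estimator form of the covariate-adjusted FDR screen.

    Parameters
    ----------
    target : str
        Behavioral column screened against (default the early-life-stress
        score).
    covariates : sequence of str
        Behavioral columns partialled out of both sides.
    q : float
        FDR level for the BH step-up over the screen family.

    Attributes
    ----------
    results_ : pandas.DataFrame
        One row per measure: ``measure, r, p, p_adj, significant``.
    significant_ : list of str
        Measures whose adjusted p-value is at most ``q``.
    """

    def __init__(
        self,
        target: str = "els",
        covariates: Sequence[str] = COVARIATES_BASIC,
        q: float = 0.05,
    ):
        self.target = target
        self.covariates = covariates
        self.q = q

    def fit(self, X: pd.DataFrame, y: pd.DataFrame) -> "CorrelationScreen":
        """Run the screen of feature frame ``X`` against behavioral table ``y``."""
        self.results_ = screen(X, y, self.target, self.covariates, self.q)
        self.significant_ = self.results_.loc[self.results_["significant"], "measure"].tolist()
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Restrict a feature frame to the measures that survived FDR."""
        return X[self.significant_]
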