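"""Simple mediation (X -> M -> Y) with bias-corrected bootstrap inference.

The three OLS equations of a single-mediator model, all sharing the same
covariate set:

    M = i1 + a * X            (+ covariates)
    Y = i2 + c' * X + b * M   (+ covariates)
    Y = i3 + c * X            (+ covariates)

X, M and Y are z-scored before fitting so ``a``, ``b``, ``c`` and ``c'``
are standardized path coefficients; covariates stay on their raw scale
(rescaling them cannot change the focal standardized paths).  The total
effect decomposes exactly as ``c = c' + a * b``.

The indirect effect ``a * b`` is tested by case resampling: subjects are
drawn with replacement, the paths refitted per resample, and a confidence
interval read from the bootstrap distribution.  The bias-corrected (BC)
method shifts the percentile positions by ``z0``, the normal quantile of
the fraction of bootstrap estimates below the point estimate (ties counted
half), reading quantiles at ``Phi(2 z0 +/- z_{1-alpha/2})``; with a
symmetric bootstrap distribution centered on the estimate ``z0 = 0`` and BC
reduces to the plain percentile interval.  An interval excluding zero
declares the indirect effect significant.  X, M and Y are standardized once
on the full sample before resampling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

_MAX_CONDITION = 1e10
_CHUNK_ELEMS = 20_000_000  # bootstrap gather buffer cap (floats)


@dataclass(frozen=True)
class PathEstimates:
    """Standardized OLS path coefficients of one mediation model."""

    a: float
    b: float
    c: float
    c_prime: float

    @property
    def indirect(self) -> float:
        return self.a * self.b


@dataclass(frozen=True)
class MediationResult:
    """Point estimates plus bootstrap CI for the indirect effect."""

    a: float
    b: float
    c: float
    c_prime: float
    indirect: float
    ci_low: float
    ci_high: float
    n_boot: int
    ci_level: float
    method: str
    significant: bool
    seed: int
    z0: float
    n_subjects: int
    n_redraws: int = 0
    pathological: bool = False

    def to_dict(self) -> dict:
        return {
            "a": self.a, "b": self.b, "c": self.c, "c_prime": self.c_prime,
            "indirect": self.indirect, "ci_low": self.ci_low, "ci_high": self.ci_high,
            "n_boot": self.n_boot, "ci_level": self.ci_level, "method": self.method,
            "significant": self.significant, "seed": self.seed, "z0": self.z0,
            "n_subjects": self.n_subjects, "n_redraws": self.n_redraws,
            "pathological": self.pathological,
        }


def _zscore(v: np.ndarray, name: str) -> np.ndarray:
    sd = v.std()
    if sd == 0:
        raise ValueError(f"{name} has zero variance")
    return (v - v.mean()) / sd


def _prepare(x, m, y, covariates):
    x = np.asarray(x, dtype=float)
    m = np.asarray(m, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (x.shape == m.shape == y.shape) or x.ndim != 1:
        raise ValueError("x, m, y must be 1-D vectors of equal length")
    n = x.size
    if covariates is None:
        cov = np.empty((n, 0))
    else:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        if cov.shape[0] != n:
            raise ValueError("covariates must have one row per subject")
    if n <= cov.shape[1] + 4:
        raise ValueError(f"need n > k + 4 subjects (n={n}, k={cov.shape[1]})")
    return _zscore(x, "x"), _zscore(m, "m"), _zscore(y, "y"), cov


def _ols(design: np.ndarray, target: np.ndarray) -> np.ndarray:
    if np.linalg.cond(design) > _MAX_CONDITION:
        raise ValueError("design matrix is ill conditioned (collinear regressors)")
    beta, *_ = np.linalg.lstsq(design, target, rcond=None)
    return beta


def fit_paths(x, m, y, covariates=None) -> PathEstimates:
    """Standardized a, b, c, c' from the three OLS equations.

    Satisfies ``c - c_prime == a * b`` to numerical precision because all
    equations share the covariate set.
    """
    xz, mz, yz, cov = _prepare(x, m, y, covariates)
    n = xz.size
    ones = np.ones(n)
    d_xm = np.column_stack([ones, xz, cov])
    d_full = np.column_stack([ones, xz, mz, cov])
    a = float(_ols(d_xm, mz)[1])
    beta = _ols(d_full, yz)
    c_prime, b = float(beta[1]), float(beta[2])
    c = float(_ols(d_xm, yz)[1])
    return PathEstimates(a=a, b=b, c=c, c_prime=c_prime)


def _bootstrap_ab(
    xz: np.ndarray, mz: np.ndarray, yz: np.ndarray, cov: np.ndarray,
    n_boot: int, rng: np.random.Generator,
) -> tuple[np.ndarray, int]:
    """Bootstrap distribution of a * b via batched normal-equation solves."""
    n = xz.size
    data = np.column_stack([np.ones(n), xz, mz, cov])  # cols: 1, x, m, cov...
    p = data.shape[1]
    cov_cols = list(range(3, p))
    idx = rng.integers(0, n, size=(n_boot, n))
    # redraw resamples with a constant x or m (degenerate designs)
    n_redraws = 0
    for _ in range(100):
        xb = xz[idx]
        bad = (xb.std(axis=1) == 0) | (mz[idx].std(axis=1) == 0)
        if not bad.any():
            break
        n_redraws += int(bad.sum())
        idx[bad] = rng.integers(0, n, size=(int(bad.sum()), n))
    else:
        raise ValueError("too many degenerate bootstrap resamples")

    ab = np.empty(n_boot)
    chunk = max(1, _CHUNK_ELEMS // (n * p))
    cols_xm = [0, 1] + cov_cols
    cols_full = [0, 1, 2] + cov_cols
    for start in range(0, n_boot, chunk):
        sl = idx[start : start + chunk]
        Db = data[sl]                       # (B, n, p)
        yb = yz[sl]
        tb = mz[sl]
        D1 = Db[:, :, cols_xm]
        G1 = np.einsum("bni,bnj->bij", D1, D1, optimize=True)
        h1 = np.einsum("bni,bn->bi", D1, tb, optimize=True)
        a_b = np.linalg.solve(G1, h1[..., None])[:, 1, 0]
        D2 = Db[:, :, cols_full]
        G2 = np.einsum("bni,bnj->bij", D2, D2, optimize=True)
        h2 = np.einsum("bni,bn->bi", D2, yb, optimize=True)
        b_b = np.linalg.solve(G2, h2[..., None])[:, 2, 0]
        ab[start : start + len(sl)] = a_b * b_b
    return ab, n_redraws


def percentile_interval(ab: np.ndarray, ci_level: float) -> tuple[float, float]:
    """Plain empirical quantile interval of a bootstrap distribution."""
    alpha = 1.0 - ci_level
    lo, hi = np.quantile(ab, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(lo), float(hi)


def bc_interval(
    ab: np.ndarray, point_estimate: float, ci_level: float
) -> tuple[float, float, float, bool]:
    """Bias-corrected quantile interval of a bootstrap distribution.

    ``z0`` is the normal quantile of the fraction of bootstrap estimates
    strictly below the point estimate, counting ties half; the interval
    reads quantiles at ``Phi(2 z0 +/- z_{1-alpha/2})``.  When the whole
    bootstrap mass lies on one side of the estimate the proportion is
    clamped and the result flagged pathological.  Returns
    ``(low, high, z0, pathological)``.
    """
    ab = np.asarray(ab, dtype=float)
    n_boot = ab.size
    alpha = 1.0 - ci_level
    z_crit = stats.norm.ppf(1.0 - alpha / 2.0)
    below = int(np.sum(ab < point_estimate))
    ties = int(np.sum(ab == point_estimate))
    prop = (below + 0.5 * ties) / n_boot
    pathological = False
    if prop <= 0.0 or prop >= 1.0:
        pathological = True
        prop = float(np.clip(prop, 1.0 / (n_boot + 1), n_boot / (n_boot + 1.0)))
    z0 = float(stats.norm.ppf(prop))
    lo_q = float(stats.norm.cdf(2.0 * z0 - z_crit))
    hi_q = float(stats.norm.cdf(2.0 * z0 + z_crit))
    lo, hi = np.quantile(ab, [lo_q, hi_q])
    return float(lo), float(hi), z0, pathological


def bootstrap_indirect(
    x, m, y, covariates=None,
    n_boot: int = 2000,
    ci_level: float = 0.95,
    method: str = "bias_corrected",
    seed: int = 0,
) -> MediationResult:
    """Case-resampling bootstrap CI for the indirect effect ``a * b``.

    ``method="bias_corrected"`` (default) applies the z0 percentile shift;
    ``"percentile"`` reads the plain empirical quantiles.  Significance is
    declared when the interval excludes zero.
    """
    if method not in ("bias_corrected", "percentile"):
        raise ValueError("method must be 'bias_corrected' or 'percentile'")
    if n_boot < 200:
        raise ValueError("need n_boot >= 200 for a bootstrap CI")
    if not 0.0 < ci_level < 1.0:
        raise ValueError("ci_level must be in (0, 1)")
    xz, mz, yz, cov = _prepare(x, m, y, covariates)
    point = fit_paths(xz, mz, yz, cov if cov.size else None)
    rng = np.random.default_rng(seed)
    ab, n_redraws = _bootstrap_ab(xz, mz, yz, cov, n_boot, rng)

    if method == "percentile":
        ci_low, ci_high = percentile_interval(ab, ci_level)
        z0, pathological = 0.0, False
    else:
        ci_low, ci_high, z0, pathological = bc_interval(ab, point.indirect, ci_level)
    if method == "bias_corrected" and not (ci_low <= point.indirect <= ci_high):
        pathological = True
    return MediationResult(
        a=point.a, b=point.b, c=point.c, c_prime=point.c_prime,
        indirect=point.indirect,
        ci_low=float(ci_low), ci_high=float(ci_high),
        n_boot=n_boot, ci_level=ci_level, method=method,
        significant=not (ci_low <= 0.0 <= ci_high),
        seed=seed, z0=z0, n_subjects=xz.size,
        n_redraws=n_redraws, pathological=pathological,
    )


class MediationModel(BaseEstimator):
    """Estimator form of the bootstrap mediation analysis.

    Parameters name the columns of the analysis table passed to ``fit``:
    ``x_col`` the exposure (early-life stress), ``m_col`` the mediator
    (a connectivity measure or an attention-bias score), ``y_col`` the
    outcome (depression), ``covariate_cols`` the adjustment set.

    Attributes (after ``fit``): ``a_``, ``b_``, ``c_``, ``c_prime_``,
    ``indirect_``, ``ci_``, ``significant_``, ``result_``.
    """

    def __init__(
        self,
        x_col: str = "els",
        m_col: str = "mediator",
        y_col: str = "depression",
        covariate_cols: Sequence[str] = ("age", "sex"),
        n_boot: int = 2000,
        ci_level: float = 0.95,
        method: str = "bias_corrected",
        seed: int = 0,
    ):
        self.x_col = x_col
        self.m_col = m_col
        self.y_col = y_col
        self.covariate_cols = covariate_cols
        self.n_boot = n_boot
        self.ci_level = ci_level
        self.method = method
        self.seed = seed

    def fit(self, X: pd.DataFrame, y=None) -> "MediationModel":
        missing = {self.x_col, self.m_col, self.y_col, *self.covariate_cols} - set(X.columns)
        if missing:
            raise ValueError(f"analysis table is missing columns: {sorted(missing)}")
        cov = X[list(self.covariate_cols)].to_numpy(dtype=float) if self.covariate_cols else None
        self.result_ = bootstrap_indirect(
            X[self.x_col], X[self.m_col], X[self.y_col], cov,
            n_boot=self.n_boot, ci_level=self.ci_level,
            method=self.method, seed=self.seed,
        )
        r = self.result_
        self.a_, self.b_, self.c_, self.c_prime_ = r.a, r.b, r.c, r.c_prime
        self.indirect_ = r.indirect
        self.ci_ = (r.ci_low, r.ci_high)
        self.significant_ = r.significant
        return self


def run_cohort_models(
    features: pd.DataFrame,
    behavior: pd.DataFrame,
    bias_scores: pd.DataFrame | None = None,
    connectivity_mediator: str = "within:VAN",
    bias_condition: str = "NS",
    covariates: Sequence[str] = ("age", "sex"),
    n_boot: int = 2000,
    ci_level: float = 0.95,
    method: str = "bias_corrected",
    seed: int = 0,
) -> dict[str, MediationResult]:
    """The two headline mediation models on one cohort.

    Model ``"van_connectivity"``: stress -> within-network connectivity of
    the ventral attention network -> depression.  Model ``"sad_bias"``
    (when dot-probe scores are supplied): stress -> attention bias to the
    sad face -> depression.  Both adjust for age and sex by default.
    """
    behavior = behavior.set_index("subject_id") if "subject_id" in behavior.columns else behavior
    if connectivity_mediator not in features.columns:
        raise ValueError(f"mediator column {connectivity_mediator!r} missing from profiles")
    common = features.index.intersection(behavior.index)
    beh = behavior.loc[common]
    cov = beh[list(covariates)].to_numpy(dtype=float) if covariates else None
    results: dict[str, MediationResult] = {}
    results["van_connectivity"] = bootstrap_indirect(
        beh["els"], features.loc[common, connectivity_mediator], beh["depression"], cov,
        n_boot=n_boot, ci_level=ci_level, method=method, seed=seed,
    )
    if bias_scores is not None:
        if bias_condition not in bias_scores.columns:
            raise ValueError(f"bias condition {bias_condition!r} missing from scores")
        scores = bias_scores[bias_condition].dropna()
        sub = behavior.index.intersection(scores.index)
        beh2 = behavior.loc[sub]
        cov2 = beh2[list(covariates)].to_numpy(dtype=float) if covariates else None
        results["sad_bias"] = bootstrap_indirect(
            beh2["els"], scores.loc[sub], beh2["depression"], cov2,
            n_boot=n_boot, ci_level=ci_level, method=method, seed=seed + 1,
        )
    return results


def render_path_diagram(result: MediationResult, x: str = "ELS", m: str = "M", y: str = "Depression") -> str:
    """Plain-text path diagram with the standardized coefficients."""
    star = "*" if result.significant else ""
    return "\n".join(
        [
            f"        {m}",
            f"   a={result.a:+.3f}   b={result.b:+.3f}",
            f"  /                \\",
            f"{x} ----------------> {y}",
            f"   c'={result.c_prime:+.3f}  (c={result.c:+.3f})",
            f"indirect a*b = {result.indirect:+.3f}{star} "
            f"[{result.ci_low:+.3f}, {result.ci_high:+.3f}] "
            f"({int(result.ci_level * 100)}% {result.method} CI, {result.n_boot} resamples)",
        ]
    )
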