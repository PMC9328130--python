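"""Single-covariate random-effects meta-regression with REML τ².

Model: es_i = β₀ + β₁ x_i + u_i + ε_i with u_i ~ N(0, τ²) and
ε_i ~ N(0, v_i), v_i the known nonparametric sampling variances. τ² is
estimated by restricted maximum likelihood, profiled over a bounded
interval [0, 10·Var(es)] with a one-dimensional bounded minimizer
(tolerance 1e-8); the coefficients are then the weighted least-squares
solution at the REML τ² with weights 1/(v_i + τ²).

Inference uses the normal (z) reference by default, matching z-style CIs
used elsewhere in the pipeline; the Knapp–Hartung small-sample adjustment
(t reference with a scaled covariance) is available behind a flag. The
model test is the Wald chi-square of the slope with 1 df.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .exceptions import DomainError

logger = logging.getLogger(__name__)

__all__ = ["MetaRegResult", "fit_meta_regression", "reml_neg2_loglik", "reml_tau2_grid"]


@dataclass(frozen=True)
class MetaRegResult:
    """Slope/intercept summary for one covariate (ln R per covariate unit)."""

    covariate: str
    k: int
    slope: float
    intercept: float
    se_slope: float
    se_intercept: float
    ci_low_slope: float
    ci_high_slope: float
    ci_low_intercept: float
    ci_high_intercept: float
    p_slope: float
    p_intercept: float
    Q_model: float
    df_model: int
    p_model: float
    tau2_reml: float

    def to_frame(self) -> pd.DataFrame:
        """Two-row table (slope, intercept) in the usual report shape."""
        return pd.DataFrame(
            [
                {
                    "term": f"slope ({self.covariate})",
                    "estimate": self.slope,
                    "se": self.se_slope,
                    "ci_low": self.ci_low_slope,
                    "ci_high": self.ci_high_slope,
                    "p": self.p_slope,
                    "Q": self.Q_model,
                    "df": self.df_model,
                    "p_model": self.p_model,
                },
                {
                    "term": "intercept",
                    "estimate": self.intercept,
                    "se": self.se_intercept,
                    "ci_low": self.ci_low_intercept,
                    "ci_high": self.ci_high_intercept,
                    "p": self.p_intercept,
                    "Q": np.nan,
                    "df": np.nan,
                    "p_model": np.nan,
                },
            ]
        )


def _wls(y: np.ndarray, X: np.ndarray, w: np.ndarray):
    """Weighted least squares; returns (beta, cov, residuals, XtWX)."""
    XtW = X.T * w
    M = XtW @ X
    beta = np.linalg.solve(M, XtW @ y)
    cov = np.linalg.inv(M)
    resid = y - X @ beta
    return beta, cov, resid, M


def reml_neg2_loglik(tau2: float, y: np.ndarray, X: np.ndarray, v: np.ndarray) -> float:
    """−2 × restricted log-likelihood of the mixed model at a given τ².

    Up to an additive constant: Σ log(v_i+τ²) + log|X'WX| + Σ w_i r_i²,
    with W = diag(1/(v_i+τ²)) and r the WLS residuals at that τ².
    """
    w = 1.0 / (v + tau2)
    _, _, resid, M = _wls(y, X, w)
    _, logdet = np.linalg.slogdet(M)
    return float(np.sum(np.log(v + tau2)) + logdet + np.sum(w * resid**2))


def reml_tau2_grid(y, X, v, upper: float | None = None, step: float = 1e-4) -> float:
    """Grid-search the REML objective over τ² ∈ [0, upper] at ``step``.

    Brute-force independent check of the profiled optimizer; O(upper/step)
    objective evaluations.
    """
    y = np.asarray(y, float)
    v = np.asarray(v, float)
    if upper is None:
        upper = max(10.0 * float(np.var(y)), 1e-3)
    grid = np.arange(0.0, upper + step, step)
    vals = [reml_neg2_loglik(t, y, X, v) for t in grid]
    return float(grid[int(np.argmin(vals))])


def fit_meta_regression(
    effects: pd.DataFrame,
    covariate: str,
    ci_level: float = 0.95,
    knapp_hartung: bool = False,
) -> MetaRegResult:
    """Fit the single-covariate REML meta-regression.

    Rows with a missing covariate are dropped (the count is logged).
    The covariate enters uncentered, so the intercept is the expected
    ln-ratio at covariate zero.

    Raises
    ------
    DomainError
        For fewer than 3 usable rows or a constant covariate.
    """
    if covariate not in effects.columns:
        raise DomainError(f"covariate {covariate!r} not present on effects")
    usable = effects[effects[covariate].notna()]
    dropped = len(effects) - len(usable)
    if dropped:
        logger.info("meta-regression on %s: dropped %d rows missing the covariate",
                    covariate, dropped)
    k = len(usable)
    if k < 3:
        raise DomainError(f"meta-regression needs >= 3 rows with {covariate!r}, got {k}")
    x = usable[covariate].to_numpy(dtype=float)
    if np.unique(x).size < 2:
        raise DomainError(f"covariate {covariate!r} is constant")
    y = usable["es"].to_numpy(dtype=float)
    v = usable["v"].to_numpy(dtype=float)
    X = np.column_stack([np.ones(k), x])

    upper = max(10.0 * float(np.var(y)), 1e-6)
    res = optimize.minimize_scalar(
        reml_neg2_loglik,
        bounds=(0.0, upper),
        args=(y, X, v),
        method="bounded",
        options={"xatol": 1e-8},
    )
    tau2 = float(res.x)
    # the bounded minimizer never evaluates exactly at the boundary
    if reml_neg2_loglik(0.0, y, X, v) <= res.fun:
        tau2 = 0.0

    w = 1.0 / (v + tau2)
    beta, cov, resid, _ = _wls(y, X, w)
    if knapp_hartung:
        scale = float(np.sum(w * resid**2) / (k - 2))
        cov = cov * scale
        crit = float(stats.t.ppf(0.5 + ci_level / 2.0, k - 2))
        sf = lambda t: 2.0 * stats.t.sf(abs(t), k - 2)
    else:
        crit = float(stats.norm.ppf(0.5 + ci_level / 2.0))
        sf = lambda z: 2.0 * stats.norm.sf(abs(z))
    se = np.sqrt(np.diag(cov))
    z = beta / se
    p = np.array([sf(val) for val in z])
    q_model = float(z[1] ** 2)
    p_model = float(stats.chi2.sf(q_model, 1)) if not knapp_hartung else float(p[1])

    return MetaRegResult(
        covariate=covariate,
        k=k,
        slope=float(beta[1]),
        intercept=float(beta[0]),
        se_slope=float(se[1]),
        se_intercept=float(se[0]),
        ci_low_slope=float(beta[1] - crit * se[1]),
        ci_high_slope=float(beta[1] + crit * se[1]),
        ci_low_intercept=float(beta[0] - crit * se[0]),
        ci_high_intercept=float(beta[0] + crit * se[0]),
        p_slope=float(p[1]),
        p_intercept=float(p[0]),
        Q_model=q_model,
        df_model=1,
        p_model=p_model,
        tau2_reml=tau2,
    )
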