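"""Log response-ratio effect sizes and nonparametric variance weights.

The effect size for one paired comparison is the natural log of the
treatment/control response ratio,

    ES = ln R = ln(X̄_CC / X̄_NCC),

negative when cover crops reduce the response. Because many field trials
report means without a dispersion estimate, each effect is weighted by the
nonparametric variance

    v = (n_CC + n_NCC) / (n_CC · n_NCC),

which depends only on replicate counts (v = 2 at the minimum n=1/1). For
reporting, log effects are back-transformed to a percentage change,
100·(exp(ES) − 1).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import DomainError
from .observations import COVARIATES, MODERATORS, ObservationSet

#: Columns of the effects frame produced by :func:`compute_effects`.
EFFECT_COLUMNS = ("article_id", "obs_id", "es", "v", "w_fixed")


def log_response_ratio(mean_cc, mean_ncc):
    """ln(mean_cc / mean_ncc); scalar or elementwise on arrays.

    Both means must be strictly positive. Negative values mean the cover
    crop reduced the response relative to the fallow control.
    """
    a = np.asarray(mean_cc, dtype=float)
    b = np.asarray(mean_ncc, dtype=float)
    if np.any(a <= 0) or np.any(b <= 0):
        raise DomainError("log response ratio requires strictly positive means")
    out = np.log(a / b)
    return float(out) if out.ndim == 0 else out


def nonparametric_variance(n_cc, n_ncc):
    """(n_cc + n_ncc)/(n_cc · n_ncc) for integer replicate counts ≥ 1.

    Strictly decreasing in each count; equals 2 at n_cc = n_ncc = 1.
    """
    a = np.asarray(n_cc)
    b = np.asarray(n_ncc)
    if not (np.issubdtype(a.dtype, np.integer) or np.all(np.mod(a, 1) == 0)):
        raise DomainError("replicate counts must be integers")
    if not (np.issubdtype(b.dtype, np.integer) or np.all(np.mod(b, 1) == 0)):
        raise DomainError("replicate counts must be integers")
    a = a.astype(float)
    b = b.astype(float)
    if np.any(a < 1) or np.any(b < 1):
        raise DomainError("replicate counts must be >= 1")
    out = (a + b) / (a * b)
    return float(out) if out.ndim == 0 else out


def percent_change(es):
    """Back-transform a log effect to a percentage change, 100·(exp(es) − 1)."""
    out = 100.0 * np.expm1(np.asarray(es, dtype=float))
    return float(out) if out.ndim == 0 else out


def compute_effects(obs_set: ObservationSet) -> pd.DataFrame:
    """Build the effects frame: one row per observation, order preserved.

    Columns: ``article_id, obs_id, es, v, w_fixed`` plus all moderators and
    covariates carried through from the observations. ``w_fixed = 1/v`` is
    the fixed-effect weight.
    """
    df = obs_set.data
    try:
        es = log_response_ratio(df["mean_cc"].to_numpy(), df["mean_ncc"].to_numpy())
        v = nonparametric_variance(df["n_cc"].to_numpy(), df["n_ncc"].to_numpy())
    except DomainError as exc:
        bad = df.loc[(df["mean_cc"] <= 0) | (df["mean_ncc"] <= 0), "obs_id"].tolist()
        raise DomainError(f"{exc} (offending obs_id: {bad[:5]})") from exc
    es = np.atleast_1d(es)
    v = np.atleast_1d(v)
    out = pd.DataFrame(
        {
            "article_id": df["article_id"].to_numpy(),
            "obs_id": df["obs_id"].to_numpy(),
            "es": es,
            "v": v,
            "w_fixed": 1.0 / v,
        }
    )
    for col in (*MODERATORS, *COVARIATES):
        out[col] = df[col].to_numpy()
    return out
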