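"""Publication-bias diagnostics: Begg–Mazumdar rank correlation and funnel data.

The Begg–Mazumdar test asks whether effect sizes drift with study precision,
the signature of selective publication. Each effect is first standardized
against the fixed-effect pooled mean,

    t_i = (es_i − ē) / sqrt(v_i − 1/Σw),      w = 1/v,

(the subtraction inside the root removes the variance the pooled mean shares
with each effect), then the Kendall rank correlation between the deviates
``t_i`` and the variances ``v_i`` is computed. Because nonparametric
variances tie heavily (every n=1/1 row has v = 2), the tie-corrected tau-b
is used, with the tie-corrected normal approximation for S and a continuity
correction. |τ| below 0.20 is conventionally read as no material asymmetry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DomainError

__all__ = ["BeggResult", "standardized_deviates", "begg_mazumdar", "funnel_data", "kendall_tau_b"]

#: Conventional |tau| threshold below which asymmetry is considered negligible.
TAU_THRESHOLD = 0.20


@dataclass(frozen=True)
class BeggResult:
    k: int
    tau: float
    z: float
    p_two_tailed: float
    threshold_flag: bool  # True when |tau| < 0.20


def standardized_deviates(es, v) -> np.ndarray:
    """Standardize effects against the fixed-effect mean.

    Returns t_i = (es_i − ē)/√(v_i − 1/Σw) with ē the fixed-effect pooled
    mean and w = 1/v. The radicand is positive whenever k ≥ 2.
    """
    es = np.asarray(es, dtype=float)
    v = np.asarray(v, dtype=float)
    if es.size < 2:
        raise DomainError("standardized deviates need at least 2 effects")
    if np.any(v <= 0):
        raise DomainError("all variances must be strictly positive")
    w = 1.0 / v
    mean = np.sum(w * es) / np.sum(w)
    var_star = v - 1.0 / np.sum(w)
    if np.any(var_star <= 0):
        raise DomainError("v_i - 1/sum(w) must be positive for all i")
    return (es - mean) / np.sqrt(var_star)


def _tie_term(x: np.ndarray, f) -> float:
    _, counts = np.unique(x, return_counts=True)
    return float(sum(f(int(t)) for t in counts if t > 1))


def kendall_tau_b(x, y) -> tuple[float, float, float]:
    """Kendall's tau-b with S and its tie-corrected variance.

    Returns ``(tau_b, S, var_S)``. S is the concordant-minus-discordant
    pair count; var_S uses the standard tie-corrected normal-approximation
    formula, which reduces to n(n−1)(2n+5)/18 without ties. tau_b is 0
    when either ranking is fully tied.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    sx = np.sign(x[:, None] - x[None, :])
    sy = np.sign(y[:, None] - y[None, :])
    S = float(np.sum(np.triu(sx * sy, k=1)))

    n0 = n * (n - 1) / 2.0
    tx = _tie_term(x, lambda t: t * (t - 1) / 2)
    ty = _tie_term(y, lambda t: t * (t - 1) / 2)
    denom = np.sqrt((n0 - tx) * (n0 - ty))
    tau = S / denom if denom > 0 else 0.0

    v0 = n * (n - 1) * (2 * n + 5)
    vt = _tie_term(x, lambda t: t * (t - 1) * (2 * t + 5))
    vu = _tie_term(y, lambda t: t * (t - 1) * (2 * t + 5))
    var_S = (v0 - vt - vu) / 18.0
    if n > 2:
        v1 = (
            _tie_term(x, lambda t: t * (t - 1))
            * _tie_term(y, lambda t: t * (t - 1))
            / (2.0 * n * (n - 1))
        )
        v2 = (
            _tie_term(x, lambda t: t * (t - 1) * (t - 2))
            * _tie_term(y, lambda t: t * (t - 1) * (t - 2))
            / (9.0 * n * (n - 1) * (n - 2))
        )
        var_S += v1 + v2
    return float(tau), S, float(var_S)


def begg_mazumdar(es, v) -> BeggResult:
    """Rank-correlation test between standardized effects and variances.

    tau is tie-corrected (tau-b); z applies a continuity correction,
    z = sign(S)·(|S| − 1)/√var(S). When all variances are identical the
    variance ranking is fully tied, tau is defined as 0 and a warning is
    issued.
    """
    es = np.asarray(es, dtype=float)
    v = np.asarray(v, dtype=float)
    k = es.size
    if k < 3:
        raise DomainError("Begg-Mazumdar test needs at least 3 effects")
    t = standardized_deviates(es, v)
    if np.unique(v).size == 1:
        warnings.warn(
            "all variances identical: variance ranking fully tied, tau set to 0",
            stacklevel=2,
        )
        return BeggResult(k=k, tau=0.0, z=0.0, p_two_tailed=1.0, threshold_flag=True)
    tau, S, var_S = kendall_tau_b(t, v)
    if var_S <= 0:
        z = 0.0
    else:
        z = np.sign(S) * max(abs(S) - 1.0, 0.0) / np.sqrt(var_S)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return BeggResult(
        k=k,
        tau=float(tau),
        z=float(z),
        p_two_tailed=p,
        threshold_flag=bool(abs(tau) < TAU_THRESHOLD),
    )


def funnel_data(effects: pd.DataFrame) -> pd.DataFrame:
    """Export funnel-plot data: (es, se) per study plus pooled reference lines.

    ``ref_fixed`` and ``ref_random`` columns repeat the fixed- and
    random-effects pooled means so the export is a single flat table.
    """
    from .pooling import pool_random

    es = effects["es"].to_numpy(dtype=float)
    v = effects["v"].to_numpy(dtype=float)
    if es.size == 0:
        raise DomainError("funnel data needs at least one effect")
    w = 1.0 / v
    fixed_mean = float(np.sum(w * es) / np.sum(w))
    random_mean = pool_random(es, v).es if es.size >= 1 else fixed_mean
    return pd.DataFrame(
        {
            "obs_id": effects["obs_id"].to_numpy(),
            "es": es,
            "se": np.sqrt(v),
            "ref_fixed": fixed_mean,
            "ref_random": random_mean,
        }
    )
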