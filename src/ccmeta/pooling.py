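"""Heterogeneity statistics and random-effects pooling.

Core quantities for a set of k effects ``es_i`` with sampling variances
``v_i`` (fixed-effect weights ``w_i = 1/v_i``):

* Cochran's Q — the weighted sum of squared deviations of the effects from
  their fixed-effect weighted mean, referred to a chi-square with k−1 df;
* I² = max(0, (Q − df)/Q · 100) — the share of observed variation due to
  true heterogeneity rather than sampling error, truncated to 0 whenever
  Q ≤ df;
* τ² — the between-study variance of true effects, estimated by the
  DerSimonian–Laird method of moments, τ² = max(0, (Q − df)/C) with
  C = Σw − Σw²/Σw;
* the random-effects pooled mean with weights ``1/(v_i + τ²)``, its normal
  95% CI, z and two-tailed p, reported alongside the back-transformed
  percentage change.

Subgroup (moderator) analysis partitions the overall Q additively into a
within-level part (the sum of per-level Qs) and a between-level part
(Q_between = Q_overall − ΣQ_within, df = #levels − 1), all computed with
fixed-effect weights; each level additionally gets its own random-effects
pooled summary with a level-specific τ² (or a τ² pooled across levels, on
request).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .effects import percent_change
from .exceptions import DomainError

__all__ = [
    "HeterogeneityResult",
    "PooledResult",
    "SubgroupTable",
    "cochran_q",
    "i_squared",
    "dl_tau2",
    "pool_random",
    "subgroup_partition",
]


@dataclass(frozen=True)
class HeterogeneityResult:
    """Cochran's Q with its df, upper-tail p and I² (percent)."""

    Q: float
    df: int
    p_hetero: float
    I2: float


@dataclass(frozen=True)
class PooledResult:
    """Random-effects pooled summary on the ln-ratio scale."""

    k: int
    es: float
    se: float
    ci_low: float
    ci_high: float
    z: float
    p: float
    tau2: float
    pct_change: float


@dataclass
class SubgroupTable:
    """Per-level heterogeneity decomposition for one moderator.

    ``rows`` has one row per level: level, n, Q, df, p_hetero, I2 plus the
    level's pooled es/se/ci/z/p/tau2/pct_change. The totals mirror the
    within/between/overall rows of a moderator table.
    """

    moderator: str
    rows: pd.DataFrame
    total_within: tuple[float, int, float]  # (Q, df, p)
    total_between: tuple[float, int, float]
    overall_het: HeterogeneityResult
    overall_pooled: PooledResult
    tau2_mode: str = "separate"

    def to_frame(self) -> pd.DataFrame:
        """Flatten to a printable table with Total within/between/Overall rows."""
        body = self.rows.copy()
        totals = pd.DataFrame(
            [
                {"level": "Total within", "Q": self.total_within[0],
                 "df": self.total_within[1], "p_hetero": self.total_within[2]},
                {"level": "Total between", "Q": self.total_between[0],
                 "df": self.total_between[1], "p_hetero": self.total_between[2]},
                {"level": "Overall", "n": self.overall_pooled.k,
                 "Q": self.overall_het.Q, "df": self.overall_het.df,
                 "p_hetero": self.overall_het.p_hetero, "I2": self.overall_het.I2,
                 "es": self.overall_pooled.es, "se": self.overall_pooled.se,
                 "ci_low": self.overall_pooled.ci_low,
                 "ci_high": self.overall_pooled.ci_high,
                 "p": self.overall_pooled.p, "tau2": self.overall_pooled.tau2,
                 "pct_change": self.overall_pooled.pct_change},
            ]
        )
        return pd.concat([body, totals], ignore_index=True)[body.columns]

    def forest_frame(self) -> pd.DataFrame:
        """Per-level forest-plot records: level,n,es,ci_low,ci_high,pct_change,p."""
        cols = ["level", "n", "es", "ci_low", "ci_high", "pct_change", "p"]
        return self.rows[cols].copy()


def _as_arrays(es, v):
    es = np.asarray(es, dtype=float)
    v = np.asarray(v, dtype=float)
    if es.ndim != 1 or es.shape != v.shape:
        raise DomainError("es and v must be 1-d arrays of equal length")
    if es.size == 0:
        raise DomainError("at least one effect is required")
    if np.any(v <= 0):
        raise DomainError("all variances must be strictly positive")
    return es, v


def cochran_q(es, v) -> HeterogeneityResult:
    """Cochran's Q of effects around their fixed-effect weighted mean.

    df = k − 1; the p-value is the upper-tail chi-square probability of Q
    (p = 1 when df = 0).
    """
    es, v = _as_arrays(es, v)
    w = 1.0 / v
    mean = np.sum(w * es) / np.sum(w)
    Q = float(np.sum(w * (es - mean) ** 2))
    df = es.size - 1
    p = float(stats.chi2.sf(Q, df)) if df > 0 else 1.0
    return HeterogeneityResult(Q=Q, df=df, p_hetero=p, I2=i_squared(Q, df))


def i_squared(Q: float, df: int) -> float:
    """I² = max(0, (Q − df)/Q · 100); 0 when Q = 0 or Q ≤ df."""
    if Q < 0:
        raise DomainError(f"Q must be non-negative, got {Q}")
    if df < 0:
        raise DomainError(f"df must be non-negative, got {df}")
    if Q == 0 or Q <= df:
        return 0.0
    return (Q - df) / Q * 100.0


def dl_tau2(es, v) -> float:
    """DerSimonian–Laird between-study variance, truncated at zero.

    τ² = max(0, (Q − df)/C) with C = Σw − Σw²/Σw and fixed-effect weights
    w = 1/v. Returns 0 (with a warning) for a single study.
    """
    es, v = _as_arrays(es, v)
    k = es.size
    if k < 2:
        warnings.warn("tau-squared is undefined for k < 2; returning 0", stacklevel=2)
        return 0.0
    w = 1.0 / v
    het = cochran_q(es, v)
    C = np.sum(w) - np.sum(w**2) / np.sum(w)
    if C <= 0:
        return 0.0
    return float(max(0.0, (het.Q - het.df) / C))


def pool_random(es, v, tau2: float | None = None, ci_level: float = 0.95) -> PooledResult:
    """Random-effects pooled estimate with weights 1/(v + τ²).

    When ``tau2`` is None it is estimated by :func:`dl_tau2` (0 for k = 1).
    The CI uses the standard-normal multiplier for ``ci_level``; p is the
    two-tailed normal probability of z = es/se.
    """
    es, v = _as_arrays(es, v)
    k = es.size
    if tau2 is None:
        tau2 = dl_tau2(es, v) if k >= 2 else 0.0
    if tau2 < 0:
        raise DomainError("tau2 must be non-negative")
    w = 1.0 / (v + tau2)
    sw = np.sum(w)
    mean = float(np.sum(w * es) / sw)
    se = float(sw**-0.5)
    zcrit = float(stats.norm.ppf(0.5 + ci_level / 2.0))
    z = mean / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return PooledResult(
        k=k,
        es=mean,
        se=se,
        ci_low=mean - zcrit * se,
        ci_high=mean + zcrit * se,
        z=float(z),
        p=p,
        tau2=float(tau2),
        pct_change=percent_change(mean),
    )


def subgroup_partition(
    effects: pd.DataFrame,
    moderator: str,
    tau2_mode: Literal["separate", "pooled"] = "separate",
    ci_level: float = 0.95,
) -> SubgroupTable:
    """Partition heterogeneity across the levels of one moderator.

    Expects an effects frame (see :func:`ccmeta.effects.compute_effects`)
    already filtered so every row carries a moderator value. Per-level Q,
    df, p and I² use fixed-effect weights; the between-level Q is the
    difference Q_overall − ΣQ_within with df = #levels − 1 (an exact
    algebraic partition). Pooled per-level summaries use a level-specific
    DL τ² by default, or one τ² estimated from all records when
    ``tau2_mode='pooled'``.
    """
    if moderator not in effects.columns:
        raise DomainError(f"moderator {moderator!r} not present on effects")
    if effects[moderator].isna().any():
        raise DomainError(
            f"moderator {moderator!r} has missing values; filter levels first"
        )
    es_all = effects["es"].to_numpy(dtype=float)
    v_all = effects["v"].to_numpy(dtype=float)
    overall_het = cochran_q(es_all, v_all)
    overall_pooled = pool_random(es_all, v_all, ci_level=ci_level)
    shared_tau2 = overall_pooled.tau2 if tau2_mode == "pooled" else None

    levels = list(pd.unique(effects[moderator]))
    rows = []
    q_within = 0.0
    df_within = 0
    for level in levels:
        sub = effects[effects[moderator] == level]
        es = sub["es"].to_numpy(dtype=float)
        v = sub["v"].to_numpy(dtype=float)
        het = cochran_q(es, v)
        pooled = pool_random(es, v, tau2=shared_tau2, ci_level=ci_level)
        q_within += het.Q
        df_within += het.df
        rows.append(
            {
                "level": level,
                "n": len(sub),
                "Q": het.Q,
                "df": het.df,
                "p_hetero": het.p_hetero,
                "I2": het.I2,
                "es": pooled.es,
                "se": pooled.se,
                "ci_low": pooled.ci_low,
                "ci_high": pooled.ci_high,
                "z": pooled.z,
                "p": pooled.p,
                "tau2": pooled.tau2,
                "pct_change": pooled.pct_change,
            }
        )

    q_between = max(0.0, overall_het.Q - q_within)
    df_between = len(levels) - 1
    p_within = float(stats.chi2.sf(q_within, df_within)) if df_within > 0 else 1.0
    p_between = float(stats.chi2.sf(q_between, df_between)) if df_between > 0 else 1.0

    return SubgroupTable(
        moderator=moderator,
        rows=pd.DataFrame(rows),
        total_within=(q_within, df_within, p_within),
        total_between=(q_between, df_between, p_between),
        overall_het=overall_het,
        overall_pooled=overall_pooled,
        tau2_mode=tau2_mode,
    )
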