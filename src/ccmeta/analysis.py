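"""Orchestration of the full per-response moderator analysis.

`run_analysis` walks an ordered list of moderators, applies the level
inclusion rule (≥ 2 levels, each backed by ≥ 3 articles), partitions
heterogeneity per moderator and pools each level under the random-effects
model. The overall pooled summary is computed once, on the unfiltered
(response-matched) effect set, so every moderator table shares the same
overall row whenever its filter drops no rows. Moderators that cannot be
analysed are recorded as skips, not failures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .effects import compute_effects
from .exceptions import DomainError, MetaError
from .observations import (
    MODERATORS,
    ObservationSet,
    filter_moderator_levels,
    write_results_table,
)
from .pooling import (
    HeterogeneityResult,
    PooledResult,
    SubgroupTable,
    cochran_q,
    pool_random,
    subgroup_partition,
)

__all__ = ["AnalysisRun", "run_analysis", "tillage_contrast", "write_run"]

#: Default moderator order for a full analysis run.
DEFAULT_MODERATORS: tuple[str, ...] = MODERATORS


@dataclass
class AnalysisRun:
    """Results of one full per-response analysis."""

    response: str
    moderators: list[str]
    tables: dict[str, SubgroupTable]
    skipped: dict[str, str]
    overall_het: HeterogeneityResult
    overall_pooled: PooledResult
    config: dict
    log: list[str] = field(default_factory=list)


def run_analysis(
    obs_set: ObservationSet,
    moderators: Sequence[str] | None = None,
    min_articles: int = 3,
    min_levels: int = 2,
    alpha_hetero: float = 0.10,
    ci_level: float = 0.95,
    tau2_mode: str = "separate",
) -> AnalysisRun:
    """Run the moderator analysis for one response.

    ``alpha_hetero`` is the heterogeneity significance convention (default
    .10, reflecting the low power of the Q test); it is recorded in the
    config snapshot and log, not used to gate any computation.
    """
    if len(obs_set) == 0:
        raise DomainError("observation set is empty")
    moderators = list(moderators) if moderators is not None else list(DEFAULT_MODERATORS)
    config = {
        "response": obs_set.response.value,
        "moderators": moderators,
        "min_articles": min_articles,
        "min_levels": min_levels,
        "alpha_hetero": alpha_hetero,
        "ci_level": ci_level,
        "tau2_mode": tau2_mode,
    }
    log: list[str] = []
    effects_all = compute_effects(obs_set)
    overall_het = cochran_q(effects_all["es"], effects_all["v"])
    overall_pooled = pool_random(effects_all["es"], effects_all["v"], ci_level=ci_level)
    log.append(
        f"overall: k={overall_pooled.k} es={overall_pooled.es:.4f} "
        f"Q={overall_het.Q:.1f} df={overall_het.df} I2={overall_het.I2:.1f}% "
        f"(heterogeneity {'significant' if overall_het.p_hetero < alpha_hetero else 'not significant'} "
        f"at alpha={alpha_hetero})"
    )

    tables: dict[str, SubgroupTable] = {}
    skipped: dict[str, str] = {}
    for moderator in moderators:
        try:
            filtered = filter_moderator_levels(
                obs_set, moderator, min_articles=min_articles, min_levels=min_levels
            )
            effects = compute_effects(filtered)
            tables[moderator] = subgroup_partition(
                effects, moderator, tau2_mode=tau2_mode, ci_level=ci_level
            )
            log.append(
                f"{moderator}: {tables[moderator].rows.shape[0]} levels, "
                f"n={len(filtered)}"
            )
        except MetaError as exc:
            skipped[moderator] = str(exc)
            log.append(f"{moderator}: skipped ({exc})")

    return AnalysisRun(
        response=obs_set.response.value,
        moderators=moderators,
        tables=tables,
        skipped=skipped,
        overall_het=overall_het,
        overall_pooled=overall_pooled,
        config=config,
        log=log,
    )


def tillage_contrast(
    obs_set: ObservationSet,
    min_articles: int = 3,
    ci_level: float = 0.95,
    tau2_mode: str = "separate",
) -> SubgroupTable:
    """Contrast cover-crop efficacy across CT/RT/NT tillage systems."""
    filtered = filter_moderator_levels(obs_set, "tillage", min_articles=min_articles)
    effects = compute_effects(filtered)
    return subgroup_partition(effects, "tillage", tau2_mode=tau2_mode, ci_level=ci_level)


def write_run(run: AnalysisRun, outdir: str | Path) -> list[Path]:
    """Write one CSV per moderator table plus overall.csv; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for moderator, table in run.tables.items():
        p = outdir / f"{moderator}.csv"
        write_results_table(table.to_frame(), p)
        written.append(p)
    overall = pd.DataFrame(
        [
            {
                "k": run.overall_pooled.k,
                "es": run.overall_pooled.es,
                "se": run.overall_pooled.se,
                "ci_low": run.overall_pooled.ci_low,
                "ci_high": run.overall_pooled.ci_high,
                "z": run.overall_pooled.z,
                "p": run.overall_pooled.p,
                "tau2": run.overall_pooled.tau2,
                "pct_change": run.overall_pooled.pct_change,
                "Q": run.overall_het.Q,
                "df": run.overall_het.df,
                "p_hetero": run.overall_het.p_hetero,
                "I2": run.overall_het.I2,
            }
        ]
    )
    p = outdir / "overall.csv"
    write_results_table(overall, p)
    written.append(p)
    return written
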