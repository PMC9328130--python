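"""Synthetic observation tables with known truth.

The generator emulates the structure of a multi-article field-trial
compilation: articles contribute batches of paired CC/NCC comparisons,
each carrying categorical moderators, numeric covariates, replicate counts
(with a large share of unreplicated n=1/1 rows) and strictly positive
treatment/control means. The sampling model is exactly the one the
analysis assumes:

    θ_i   = Σ_m μ[level_m(i)] + β_rain·(rain_i − mid) + β_temp·(temp_i − mid)
            + a_article(i) + N(0, τ²)
    X̄_NCC ~ log-normal(meanlog, sdlog)
    X̄_CC  = X̄_NCC · exp(θ_i) · exp(ε_i),   ε_i ~ N(0, v_i)

with v_i the nonparametric variance implied by the drawn replicate counts.
Level means are additive across moderators; in the shipped default
configuration only the cover-crop family carries nonzero means, so each
moderator's subgroup truth is unambiguous. Covariate slopes act on
covariates centered at their range midpoint, so the configured level means
are also the level truths when slopes are nonzero. Moderator labels can be
masked at random (``missing_prob``) after the true effect is drawn — the
hidden level still shapes the effect, as an unreported soil type would in
real data. The genus label is drawn conditionally on the family from a
fixed nesting so tables are biologically coherent.

Everything is reproducible from the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .analysis import AnalysisRun
from .exceptions import ConfigError, DomainError
from .metareg import MetaRegResult
from .observations import ObservationSet, Response

__all__ = ["LevelSpec", "ModeratorSpec", "CovariateSpec", "SimConfig",
           "generate", "recovery_report", "default_config"]


@dataclass(frozen=True)
class LevelSpec:
    """One moderator level: sampling probability and true ln-ratio mean."""

    prob: float
    mu: float = 0.0


@dataclass(frozen=True)
class ModeratorSpec:
    levels: Mapping[str, LevelSpec]
    missing_prob: float = 0.0


@dataclass(frozen=True)
class CovariateSpec:
    rainfall_range: tuple[float, float] = (300.0, 1400.0)
    temp_range: tuple[float, float] = (4.0, 18.0)
    slope_rainfall: float = 0.0  # ln R per mm
    slope_temp: float = 0.0  # ln R per °C


@dataclass(frozen=True)
class SimConfig:
    """Full description of a synthetic observation table."""

    response: Response = Response.NITRATE_LEACHING
    n_articles: int = 41
    obs_per_article: tuple[int, int] = (14, 40)
    tau2: float = 0.3
    sigma2_article: float = 0.0  # optional article-level random effect
    baseline_meanlog: float = math.log(30.0)  # control means, log-normal
    baseline_sdlog: float = 1.0
    replicate_dist: tuple[tuple[tuple[int, int], float], ...] = (
        ((1, 1), 0.60),
        ((2, 2), 0.05),
        ((3, 3), 0.15),
        ((4, 4), 0.15),
        ((3, 4), 0.05),
    )
    subgroups: Mapping[str, ModeratorSpec] = field(default_factory=dict)
    genus_by_family: Mapping[str, Mapping[str, float]] | None = None
    covariates: CovariateSpec = CovariateSpec()
    seed: int = 0

    def validate(self) -> None:
        if self.n_articles < 1:
            raise ConfigError("n_articles must be >= 1")
        lo, hi = self.obs_per_article
        if not (1 <= lo <= hi):
            raise ConfigError("obs_per_article must be an ordered range of integers >= 1")
        if self.tau2 < 0 or self.sigma2_article < 0:
            raise ConfigError("variance components must be non-negative")
        if self.baseline_sdlog <= 0:
            raise ConfigError("baseline_sdlog must be positive")
        probs = [p for (_, _), p in
                 (((a, b), p) for (a, b), p in self.replicate_dist)]
        if abs(sum(probs) - 1.0) > 1e-8 or any(p < 0 for p in probs):
            raise ConfigError("replicate_dist probabilities must be >= 0 and sum to 1")
        if any(n < 1 for (pair, _) in self.replicate_dist for n in pair):
            raise ConfigError("replicate counts must be >= 1")
        for name, spec in self.subgroups.items():
            s = sum(l.prob for l in spec.levels.values())
            if abs(s - 1.0) > 1e-8 or any(l.prob < 0 for l in spec.levels.values()):
                raise ConfigError(f"level probabilities for {name!r} must sum to 1")
            if not (0.0 <= spec.missing_prob < 1.0):
                raise ConfigError(f"missing_prob for {name!r} must be in [0, 1)")
        if self.genus_by_family is not None:
            for fam, genera in self.genus_by_family.items():
                if not genera or any(w <= 0 for w in genera.values()):
                    raise ConfigError(f"genus weights for family {fam!r} must be positive")


def _normalize_levels(raw: Mapping) -> dict[str, LevelSpec]:
    """Turn a YAML level mapping (weights + optional mean_ratio/mu) into LevelSpecs."""
    weights = {}
    mus = {}
    for name, entry in raw.items():
        entry = dict(entry)
        weights[name] = float(entry.pop("weight", entry.pop("prob", 1.0)))
        if "mean_ratio" in entry:
            ratio = float(entry.pop("mean_ratio"))
            if ratio <= 0:
                raise ConfigError(f"mean_ratio for level {name!r} must be positive")
            mus[name] = math.log(ratio)
        else:
            mus[name] = float(entry.pop("mu", 0.0))
        if entry:
            raise ConfigError(f"unknown keys for level {name!r}: {sorted(entry)}")
    total = sum(weights.values())
    if total <= 0:
        raise ConfigError("level weights must be positive")
    return {
        name: LevelSpec(prob=weights[name] / total, mu=mus[name]) for name in weights
    }


def config_from_dict(raw: Mapping) -> SimConfig:
    """Build a SimConfig from a plain mapping (the YAML file layout)."""
    raw = dict(raw)
    subgroups = {}
    for mod, spec in raw.pop("subgroups", {}).items():
        spec = dict(spec)
        subgroups[mod] = ModeratorSpec(
            levels=_normalize_levels(spec.pop("levels")),
            missing_prob=float(spec.pop("missing_prob", 0.0)),
        )
        if spec:
            raise ConfigError(f"unknown keys for moderator {mod!r}: {sorted(spec)}")
    cov_raw = dict(raw.pop("covariates", {}))
    covariates = CovariateSpec(
        rainfall_range=tuple(cov_raw.pop("rainfall_range", (300.0, 1400.0))),
        temp_range=tuple(cov_raw.pop("temp_range", (4.0, 18.0))),
        slope_rainfall=float(cov_raw.pop("slope_rainfall", 0.0)),
        slope_temp=float(cov_raw.pop("slope_temp", 0.0)),
    )
    if cov_raw:
        raise ConfigError(f"unknown covariate keys: {sorted(cov_raw)}")
    baseline = dict(raw.pop("baseline_ncc", {}))
    rep = raw.pop("replicate_dist", None)
    kwargs: dict = {
        "subgroups": subgroups,
        "covariates": covariates,
        "genus_by_family": raw.pop("genus_by_family", None),
    }
    if "response" in raw:
        kwargs["response"] = Response(raw.pop("response"))
    for key in ("n_articles", "tau2", "sigma2_article", "seed"):
        if key in raw:
            kwargs[key] = raw.pop(key)
    if "obs_per_article" in raw:
        kwargs["obs_per_article"] = tuple(raw.pop("obs_per_article"))
    if baseline:
        kwargs["baseline_meanlog"] = float(baseline.get("meanlog"))
        kwargs["baseline_sdlog"] = float(baseline.get("sdlog"))
    if rep is not None:
        kwargs["replicate_dist"] = tuple(
            ((int(e["n_cc"]), int(e["n_ncc"])), float(e["prob"])) for e in rep
        )
    if raw:
        raise ConfigError(f"unknown config keys: {sorted(raw)}")
    cfg = SimConfig(**kwargs)
    cfg.validate()
    return cfg


def load_config(path: str | Path) -> SimConfig:
    """Load a SimConfig from a YAML file."""
    with open(path, "r", encoding="utf-8") as fh:
        return config_from_dict(yaml.safe_load(fh))


def default_config(response: Response | str = Response.NITRATE_LEACHING) -> SimConfig:
    """The shipped default configuration for one response variable.

    Mirrors the marginal structure of the compiled study table: 41 articles
    with 14–40 observations each, five cover-crop families (with nonzero
    level means only on family), six soil orders, eight textures, eleven
    main crops, three tillage systems, ~60% unreplicated rows.
    """
    response = Response(response)
    name = (
        "leaching_default.yaml"
        if response is Response.NITRATE_LEACHING
        else "drainage_default.yaml"
    )
    text = resources.files("ccmeta").joinpath("configs", name).read_text(encoding="utf-8")
    return config_from_dict(yaml.safe_load(text))


def generate(config: SimConfig, seed: int | None = None) -> ObservationSet:
    """Draw one synthetic observation table; fully reproducible from the seed."""
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)

    counts = rng.integers(
        config.obs_per_article[0], config.obs_per_article[1] + 1, size=config.n_articles
    )
    n_total = int(np.sum(counts))
    article_idx = np.repeat(np.arange(config.n_articles), counts)
    article_ids = np.array([f"a{i + 1:03d}" for i in range(config.n_articles)])

    theta = np.zeros(n_total)
    columns: dict[str, np.ndarray] = {}

    # independent categorical moderators (genus handled below if nested)
    for mod, spec in config.subgroups.items():
        if mod == "cc_genus" and config.genus_by_family is not None:
            continue
        names = list(spec.levels)
        probs = np.array([spec.levels[n].prob for n in names])
        mus = np.array([spec.levels[n].mu for n in names])
        idx = rng.choice(len(names), size=n_total, p=probs)
        theta += mus[idx]
        labels = np.array(names, dtype=object)[idx]
        if spec.missing_prob > 0:
            labels = labels.copy()
            labels[rng.random(n_total) < spec.missing_prob] = np.nan
        columns[mod] = labels

    if config.genus_by_family is not None and "cc_family" in columns:
        genus_mu = {}
        if "cc_genus" in config.subgroups:
            genus_mu = {n: l.mu for n, l in config.subgroups["cc_genus"].levels.items()}
        genus = np.full(n_total, np.nan, dtype=object)
        fam_col = columns["cc_family"]
        for fam, genera in config.genus_by_family.items():
            mask = np.array([f == fam for f in fam_col])
            m = int(mask.sum())
            if m == 0:
                continue
            names = list(genera)
            w = np.array([genera[n] for n in names], dtype=float)
            idx = rng.choice(len(names), size=m, p=w / w.sum())
            genus[mask] = np.array(names, dtype=object)[idx]
            theta[mask] += np.array([genus_mu.get(n, 0.0) for n in names])[idx]
        missing = config.subgroups.get("cc_genus", ModeratorSpec(levels={})).missing_prob
        if missing > 0:
            genus[rng.random(n_total) < missing] = np.nan
        columns["cc_genus"] = genus

    cov = config.covariates
    rain = rng.uniform(*cov.rainfall_range, size=n_total)
    temp = rng.uniform(*cov.temp_range, size=n_total)
    theta += cov.slope_rainfall * (rain - np.mean(cov.rainfall_range))
    theta += cov.slope_temp * (temp - np.mean(cov.temp_range))

    if config.sigma2_article > 0:
        a = rng.normal(0.0, math.sqrt(config.sigma2_article), size=config.n_articles)
        theta += a[article_idx]
    theta += rng.normal(0.0, math.sqrt(config.tau2), size=n_total)

    pairs = np.array([pair for pair, _ in config.replicate_dist])
    pprob = np.array([p for _, p in config.replicate_dist])
    pick = rng.choice(len(pairs), size=n_total, p=pprob)
    n_cc = pairs[pick, 0]
    n_ncc = pairs[pick, 1]
    v = (n_cc + n_ncc) / (n_cc * n_ncc)

    eps = rng.normal(0.0, np.sqrt(v))
    mean_ncc = rng.lognormal(config.baseline_meanlog, config.baseline_sdlog, size=n_total)
    mean_cc = mean_ncc * np.exp(theta + eps)

    df = pd.DataFrame(
        {
            "article_id": article_ids[article_idx],
            "obs_id": [f"obs{i + 1:05d}" for i in range(n_total)],
            "response": config.response.value,
            "mean_cc": mean_cc,
            "mean_ncc": mean_ncc,
            "n_cc": n_cc,
            "n_ncc": n_ncc,
        }
    )
    for mod in ("cc_family", "cc_genus", "soil_order", "soil_texture", "main_crop", "tillage"):
        df[mod] = columns.get(mod, np.full(n_total, np.nan, dtype=object))
    df["rainfall_mm"] = rain
    df["temp_c"] = temp
    return ObservationSet(data=df, provenance=f"synthetic (seed={config.seed if seed is None else seed})")


def _family_of_genus(config: SimConfig) -> dict[str, str]:
    if config.genus_by_family is None:
        return {}
    return {g: fam for fam, genera in config.genus_by_family.items() for g in genera}


def theta_moments(config: SimConfig) -> tuple[float, float]:
    """Mean and variance of the systematic true-effect part θ_sys.

    Sums means/variances over independent moderators, treats the nested
    family→genus pair jointly, and adds the uniform-covariate slope
    variance. Excludes the residual τ² and article effect.
    """
    mean = 0.0
    var = 0.0
    for mod, spec in config.subgroups.items():
        if mod in ("cc_family", "cc_genus") and config.genus_by_family is not None:
            continue
        mus = np.array([l.mu for l in spec.levels.values()])
        probs = np.array([l.prob for l in spec.levels.values()])
        m = float(np.sum(probs * mus))
        mean += m
        var += float(np.sum(probs * (mus - m) ** 2))
    if config.genus_by_family is not None and "cc_family" in config.subgroups:
        fam_spec = config.subgroups["cc_family"]
        genus_mu = {
            n: l.mu for n, l in config.subgroups.get(
                "cc_genus", ModeratorSpec(levels={})).levels.items()
        }
        vals, probs = [], []
        for fam, lvl in fam_spec.levels.items():
            genera = config.genus_by_family.get(fam, {fam: 1.0})
            wsum = sum(genera.values())
            for g, w in genera.items():
                vals.append(lvl.mu + genus_mu.get(g, 0.0))
                probs.append(lvl.prob * w / wsum)
        vals = np.array(vals)
        probs = np.array(probs)
        m = float(np.sum(probs * vals))
        mean += m
        var += float(np.sum(probs * (vals - m) ** 2))
    cov = config.covariates
    var += cov.slope_rainfall**2 * (cov.rainfall_range[1] - cov.rainfall_range[0]) ** 2 / 12.0
    var += cov.slope_temp**2 * (cov.temp_range[1] - cov.temp_range[0]) ** 2 / 12.0
    return mean, var


def level_truth(config: SimConfig, moderator: str, level: str) -> float:
    """True mean ln-ratio for one moderator level (marginal over the rest)."""
    mean_all, _ = theta_moments(config)
    if moderator == "cc_genus" and config.genus_by_family is not None:
        fam = _family_of_genus(config).get(level)
        if fam is None:
            raise DomainError(f"genus {level!r} not in the nesting")
        fam_spec = config.subgroups["cc_family"]
        genus_mu = {
            n: l.mu for n, l in config.subgroups.get(
                "cc_genus", ModeratorSpec(levels={})).levels.items()
        }
        own = fam_spec.levels[fam].mu + genus_mu.get(level, 0.0)
        # remove the family+genus contribution from the grand mean
        joint_mean = 0.0
        for f, lvl in fam_spec.levels.items():
            genera = config.genus_by_family.get(f, {f: 1.0})
            wsum = sum(genera.values())
            joint_mean += lvl.prob * sum(
                (lvl.mu + genus_mu.get(g, 0.0)) * w / wsum for g, w in genera.items()
            )
        return mean_all - joint_mean + own
    if moderator not in config.subgroups:
        raise DomainError(f"moderator {moderator!r} not in the simulation config")
    spec = config.subgroups[moderator]
    if level not in spec.levels:
        raise DomainError(f"level {level!r} not configured for {moderator!r}")
    if moderator == "cc_family" and config.genus_by_family is not None:
        # family contribution includes the (zero-mean by default) genus offsets
        genus_mu = {
            n: l.mu for n, l in config.subgroups.get(
                "cc_genus", ModeratorSpec(levels={})).levels.items()
        }
        genera = config.genus_by_family.get(level, {level: 1.0})
        wsum = sum(genera.values())
        own = spec.levels[level].mu + sum(
            genus_mu.get(g, 0.0) * w / wsum for g, w in genera.items()
        )
        joint_mean = 0.0
        for f, lvl in spec.levels.items():
            gs = config.genus_by_family.get(f, {f: 1.0})
            ws = sum(gs.values())
            joint_mean += lvl.prob * sum(
                (lvl.mu + genus_mu.get(g, 0.0)) * w / ws for g, w in gs.items()
            )
        return mean_all - joint_mean + own
    mus = np.array([l.mu for l in spec.levels.values()])
    probs = np.array([l.prob for l in spec.levels.values()])
    own_mean = float(np.sum(probs * mus))
    return mean_all - own_mean + spec.levels[level].mu


def recovery_report(
    truth: SimConfig,
    run: AnalysisRun,
    metareg: list[MetaRegResult] | None = None,
) -> pd.DataFrame:
    """Tabulate estimates against the generating truth.

    One row per compared parameter: overall %change, each analysed
    moderator level's %change, the marginal τ² (generating τ² plus the
    variance of the systematic mean structure), and any supplied
    meta-regression slopes. ``within_ci`` is NaN for τ², which carries no
    interval here.
    """
    mean_sys, var_sys = theta_moments(truth)
    rows = []

    def pct(mu: float) -> float:
        return 100.0 * (math.exp(mu) - 1.0)

    op = run.overall_pooled
    rows.append(
        {
            "parameter": "overall_pct_change",
            "truth": pct(mean_sys),
            "estimate": op.pct_change,
            "abs_error": abs(op.pct_change - pct(mean_sys)),
            "within_ci": bool(pct(op.ci_low) <= pct(mean_sys) <= pct(op.ci_high)),
        }
    )
    for mod, table in run.tables.items():
        for _, r in table.rows.iterrows():
            try:
                t = level_truth(truth, mod, r["level"])
            except DomainError:
                raise DomainError(
                    f"analysis moderator {mod!r} level {r['level']!r} has no simulated truth"
                )
            rows.append(
                {
                    "parameter": f"{mod}:{r['level']}_pct_change",
                    "truth": pct(t),
                    "estimate": r["pct_change"],
                    "abs_error": abs(r["pct_change"] - pct(t)),
                    "within_ci": bool(pct(r["ci_low"]) <= pct(t) <= pct(r["ci_high"])),
                }
            )
    tau2_marginal = truth.tau2 + truth.sigma2_article + var_sys
    rows.append(
        {
            "parameter": "tau2_marginal",
            "truth": tau2_marginal,
            "estimate": op.tau2,
            "abs_error": abs(op.tau2 - tau2_marginal),
            "within_ci": np.nan,
        }
    )
    for mr in metareg or []:
        slope_truth = (
            truth.covariates.slope_rainfall
            if mr.covariate == "rainfall_mm"
            else truth.covariates.slope_temp
        )
        rows.append(
            {
                "parameter": f"slope_{mr.covariate}",
                "truth": slope_truth,
                "estimate": mr.slope,
                "abs_error": abs(mr.slope - slope_truth),
                "within_ci": bool(mr.ci_low_slope <= slope_truth <= mr.ci_high_slope),
            }
        )
    return pd.DataFrame(rows)
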