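import math

import numpy as np
import pandas as pd
import pytest

from ccmeta import (
    ConfigError,
    DomainError,
    Response,
    default_config,
    generate,
    recovery_report,
    run_analysis,
)
from ccmeta.simulate import (
    LevelSpec,
    ModeratorSpec,
    SimConfig,
    config_from_dict,
    level_truth,
    theta_moments,
)


def single_level_config(mu, tau2=0.0, reps=((1, 1), 1.0), n_articles=10, obs=(50, 50), seed=0):
    return SimConfig(
        n_articles=n_articles,
        obs_per_article=obs,
        tau2=tau2,
        replicate_dist=(reps,) if isinstance(reps[0], tuple) else (reps,),
        subgroups={"cc_family": ModeratorSpec(levels={"Only": LevelSpec(1.0, mu)})},
        seed=seed,
    )


class TestGenerate:
    def test_same_seed_identical_tables(self):
        cfg = default_config(Response.NITRATE_LEACHING)
        a = generate(cfg, seed=3)
        b = generate(cfg, seed=3)
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_different_seeds_differ(self):
        cfg = default_config(Response.NITRATE_LEACHING)
        a = generate(cfg, seed=3)
        b = generate(cfg, seed=4)
        assert not a.data["mean_cc"].equals(b.data["mean_cc"])

    def test_noise_free_limit_concentrates_at_truth(self):
        # tau2=0 and huge replicate counts: es ~= ln(0.31) for every row
        cfg = single_level_config(math.log(0.31), reps=((2000, 2000), 1.0))
        obs = generate(cfg)
        es = np.log(obs.data["mean_cc"] / obs.data["mean_ncc"])
        assert np.allclose(es, math.log(0.31), atol=0.2)
        assert abs(es.mean() - math.log(0.31)) < 0.01

    def test_means_positive_and_variances_match_counts(self):
        cfg = default_config(Response.NITRATE_LEACHING)
        obs = generate(cfg, seed=11)
        assert (obs.data["mean_cc"] > 0).all()
        assert (obs.data["mean_ncc"] > 0).all()
        pairs = {pair for pair, _ in cfg.replicate_dist}
        assert set(zip(obs.data["n_cc"], obs.data["n_ncc"])) <= pairs

    def test_marginal_structure_of_default_config(self):
        cfg = default_config(Response.NITRATE_LEACHING)
        obs = generate(cfg, seed=5)
        df = obs.data
        assert df["article_id"].nunique() == 41
        assert 41 * 14 <= len(df) <= 41 * 40
        assert df["cc_family"].nunique() == 5
        assert df["cc_genus"].nunique() >= 12
        # ~60% unreplicated rows
        frac_n1 = ((df["n_cc"] == 1) & (df["n_ncc"] == 1)).mean()
        assert 0.55 < frac_n1 < 0.65

    def test_genus_nested_within_family(self):
        cfg = default_config(Response.NITRATE_LEACHING)
        obs = generate(cfg, seed=2)
        df = obs.data.dropna(subset=["cc_family", "cc_genus"])
        fam_of = {g: f for f, gs in cfg.genus_by_family.items() for g in gs}
        assert all(fam_of[g] == f for f, g in zip(df["cc_family"], df["cc_genus"]))

    def test_within_level_es_variance_converges_to_tau2_plus_mean_v(self):
        # law of large numbers: Var(es) -> tau2 + E[v] within a single level
        cfg = SimConfig(
            n_articles=100,
            obs_per_article=(1000, 1000),
            tau2=0.25,
            subgroups={"cc_family": ModeratorSpec(levels={"Only": LevelSpec(1.0, -0.8)})},
            seed=13,
        )
        obs = generate(cfg)
        assert len(obs) == 100_000
        es = np.log(obs.data["mean_cc"] / obs.data["mean_ncc"])
        expected = cfg.tau2 + sum(
            (a + b) / (a * b) * p for (a, b), p in cfg.replicate_dist
        )
        assert np.var(es) == pytest.approx(expected, rel=0.05)

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ConfigError):
            SimConfig(
                subgroups={
                    "cc_family": ModeratorSpec(
                        levels={"A": LevelSpec(0.7), "B": LevelSpec(0.7)}
                    )
                }
            ).validate()

    def test_config_from_dict_normalizes_weights(self):
        cfg = config_from_dict(
            {
                "n_articles": 4,
                "obs_per_article": [2, 3],
                "subgroups": {
                    "cc_family": {
                        "levels": {
                            "A": {"weight": 3, "mean_ratio": 0.5},
                            "B": {"weight": 1},
                        }
                    }
                },
            }
        )
        lv = cfg.subgroups["cc_family"].levels
        assert lv["A"].prob == pytest.approx(0.75)
        assert lv["A"].mu == pytest.approx(math.log(0.5))
        assert lv["B"].mu == 0.0


class TestTruthAccounting:
    def test_theta_moments_single_moderator(self):
        cfg = SimConfig(
            subgroups={
                "cc_family": ModeratorSpec(
                    levels={"A": LevelSpec(0.5, -1.0), "B": LevelSpec(0.5, 1.0)}
                )
            }
        )
        mean, var = theta_moments(cfg)
        assert mean == pytest.approx(0.0)
        assert var == pytest.approx(1.0)

    def test_level_truth_marginalizes_other_moderators(self):
        cfg = SimConfig(
            subgroups={
                "cc_family": ModeratorSpec(
                    levels={"A": LevelSpec(0.5, -1.0), "B": LevelSpec(0.5, 0.0)}
                ),
                "tillage": ModeratorSpec(
                    levels={"CT": LevelSpec(0.5, -0.2), "NT": LevelSpec(0.5, 0.0)}
                ),
            }
        )
        # truth for family A = mu_A + mean tillage contribution
        assert level_truth(cfg, "cc_family", "A") == pytest.approx(-1.0 - 0.1)
        assert level_truth(cfg, "tillage", "CT") == pytest.approx(-0.2 - 0.5)


class TestRecoveryReport:
    def test_degenerate_config_recovers_exactly(self):
        cfg = single_level_config(math.log(0.31), reps=((2000, 2000), 1.0), obs=(200, 200))
        obs = generate(cfg)
        # add a second family so the moderator is analysable
        run = run_analysis(obs, moderators=[])
        rep = recovery_report(cfg, run)
        overall = rep[rep["parameter"] == "overall_pct_change"].iloc[0]
        assert overall["truth"] == pytest.approx(-69.0)
        assert overall["abs_error"] < 0.5
        assert bool(overall["within_ci"])

    def test_mismatched_moderator_raises(self):
        cfg = SimConfig(
            n_articles=6,
            obs_per_article=(10, 12),
            tau2=0.1,
            subgroups={
                "cc_family": ModeratorSpec(
                    levels={"A": LevelSpec(0.5, -0.5), "B": LevelSpec(0.5, 0.0)}
                )
            },
            seed=3,
        )
        run = run_analysis(generate(cfg), moderators=["cc_family"])
        assert "cc_family" in run.tables
        other = SimConfig(subgroups={})  # truth lacking the analysed moderator
        with pytest.raises(DomainError):
            recovery_report(other, run)

    def test_slope_recovery_row(self):
        from ccmeta import compute_effects, fit_meta_regression
        from ccmeta.simulate import CovariateSpec

        cfg = SimConfig(
            n_articles=20,
            obs_per_article=(50, 60),
            tau2=0.2,
            subgroups={"cc_family": ModeratorSpec(levels={"Only": LevelSpec(1.0, -1.0)})},
            covariates=CovariateSpec(slope_rainfall=0.001),
            seed=77,
        )
        obs = generate(cfg)
        run = run_analysis(obs, moderators=[])
        mr = fit_meta_regression(compute_effects(obs), "rainfall_mm")
        rep = recovery_report(cfg, run, metareg=[mr])
        row = rep[rep["parameter"] == "slope_rainfall_mm"].iloc[0]
        assert row["truth"] == 0.001
        assert row["abs_error"] < 3 * mr.se_slope
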