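import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ccmeta import (
    DomainError,
    cochran_q,
    dl_tau2,
    i_squared,
    pool_random,
    subgroup_partition,
)


class TestCochranQ:
    def test_symmetric_pair(self):
        het = cochran_q([-1.0, 1.0], [1.0, 1.0])
        assert het.Q == pytest.approx(2.0)
        assert het.df == 1

    def test_homogeneous_effects_give_zero(self):
        het = cochran_q([0.3] * 5, [2.0, 1.0, 0.5, 2.0, 1.0])
        assert het.Q == pytest.approx(0.0, abs=1e-12)
        assert het.I2 == 0.0

    def test_single_record_degenerate(self):
        het = cochran_q([0.5], [2.0])
        assert (het.Q, het.df, het.p_hetero) == (0.0, 0, 1.0)

    def test_empty_is_domain_error(self):
        with pytest.raises(DomainError):
            cochran_q([], [])


class TestISquared:
    def test_truncates_at_zero_when_q_below_df(self):
        assert i_squared(2.0, 9) == 0.0
        assert i_squared(0.0, 0) == 0.0

    def test_monotone_in_q_at_fixed_df(self):
        vals = [i_squared(q, 50) for q in np.linspace(51, 500, 20)]
        assert all(b > a for a, b in zip(vals, vals[1:]))
        assert all(0.0 <= v < 100.0 for v in vals)

    def test_negative_q_rejected(self):
        with pytest.raises(DomainError):
            i_squared(-1.0, 3)


class TestDLTau2:
    def test_hand_example(self):
        # Q=2, df=1, C = 2 - 2/2 = 1
        assert dl_tau2([-1.0, 1.0], [1.0, 1.0]) == pytest.approx(1.0)

    def test_truncation_when_q_below_df(self):
        assert dl_tau2([0.1, 0.1, 0.1], [1.0, 1.0, 1.0]) == 0.0

    def test_single_study_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            assert dl_tau2([1.0], [1.0]) == 0.0

    def test_matches_statsmodels(self):
        sm_meta = pytest.importorskip("statsmodels.stats.meta_analysis")
        rng = np.random.default_rng(3)
        es = rng.normal(size=25)
        v = rng.uniform(0.2, 2.0, size=25)
        res = sm_meta.combine_effects(es, v, method_re="dl")
        # statsmodels leaves the moment estimate untruncated; ours clips at 0
        assert dl_tau2(es, v) == pytest.approx(max(0.0, res.tau2), rel=1e-10)


class TestPoolRandom:
    def test_symmetric_pair(self):
        p = pool_random([-1.0, 1.0], [1.0, 1.0])
        assert p.es == pytest.approx(0.0)
        assert p.se == pytest.approx(1.0)  # tau2=1, w*=0.5 each
        assert p.ci_low == pytest.approx(-1.959964, abs=1e-5)
        assert p.ci_high == pytest.approx(1.959964, abs=1e-5)
        assert p.pct_change == pytest.approx(0.0)

    def test_single_study(self):
        p = pool_random([0.7], [2.0])
        assert p.es == 0.7
        assert p.tau2 == 0.0
        assert p.se == pytest.approx(np.sqrt(2.0))

    def test_equal_weights_reduce_to_arithmetic_mean(self):
        es = [0.1, 0.2, 0.3, 0.4]
        p = pool_random(es, [1.0] * 4, tau2=0.0)
        assert p.es == pytest.approx(np.mean(es))

    def test_fixed_effect_oracle_when_tau2_zero(self):
        rng = np.random.default_rng(11)
        es = rng.normal(size=30)
        v = rng.uniform(0.3, 2.0, size=30)
        p = pool_random(es, v, tau2=0.0)
        w = 1.0 / v
        assert p.es == pytest.approx(np.sum(w * es) / np.sum(w), rel=1e-12)
        assert p.se == pytest.approx(np.sum(w) ** -0.5, rel=1e-12)

    def test_matches_statsmodels_random_effects(self):
        sm_meta = pytest.importorskip("statsmodels.stats.meta_analysis")
        rng = np.random.default_rng(5)
        v = rng.uniform(0.2, 2.0, size=40)
        es = rng.normal(-0.5, np.sqrt(v + 0.5))  # genuinely heterogeneous
        ours = pool_random(es, v)
        theirs = sm_meta.combine_effects(es, v, method_re="dl")
        assert ours.es == pytest.approx(theirs.mean_effect_re, rel=1e-10)
        assert ours.se == pytest.approx(theirs.sd_eff_w_re, rel=1e-10)

    def test_ci_bounds_bracket_estimate(self):
        p = pool_random([0.2, -0.1, 0.5], [1.0, 0.5, 2.0])
        assert p.ci_low <= p.es <= p.ci_high


class TestSubgroupPartition:
    def test_hand_partition_two_identical_levels(self, effects_frame):
        # es={-1,1} in both levels, v=1 everywhere: within 2+2, between 0
        eff = effects_frame([-1, 1, -1, 1], [1, 1, 1, 1], cc_family=list("AABB"))
        tab = subgroup_partition(eff, "cc_family")
        assert tab.total_within[0] == pytest.approx(4.0)
        assert tab.total_between[0] == pytest.approx(0.0, abs=1e-12)
        assert tab.overall_het.Q == pytest.approx(4.0)
        assert tab.total_between[1] == 1

    def test_q_and_df_additivity_random_data(self, effects_frame):
        rng = np.random.default_rng(23)
        n = 200
        eff = effects_frame(
            rng.normal(size=n),
            rng.uniform(0.3, 2.0, size=n),
            cc_family=rng.choice(list("ABCDE"), size=n),
        )
        tab = subgroup_partition(eff, "cc_family")
        assert tab.total_within[0] + tab.total_between[0] == pytest.approx(
            tab.overall_het.Q, rel=1e-9
        )
        level_df = int(tab.rows["df"].sum())
        assert level_df + (len(tab.rows) - 1) == tab.overall_het.df
        assert int(tab.rows["n"].sum()) == tab.overall_pooled.k

    def test_between_shift_detected(self, effects_frame):
        eff = effects_frame(
            [-1.0, -1.1, -0.9, 1.0, 1.1, 0.9],
            [0.5] * 6,
            soil_order=["X"] * 3 + ["Y"] * 3,
        )
        tab = subgroup_partition(eff, "soil_order")
        assert tab.total_between[0] > tab.total_within[0]
        assert tab.total_between[2] < 0.01  # between-group p

    def test_pooled_tau2_mode_shares_tau2(self, effects_frame):
        rng = np.random.default_rng(4)
        eff = effects_frame(
            rng.normal(size=60), rng.uniform(0.3, 2, size=60),
            cc_family=rng.choice(list("AB"), size=60),
        )
        tab = subgroup_partition(eff, "cc_family", tau2_mode="pooled")
        assert tab.rows["tau2"].nunique() == 1
        assert tab.rows["tau2"].iloc[0] == pytest.approx(tab.overall_pooled.tau2)

    def test_missing_moderator_values_rejected(self, effects_frame):
        eff = effects_frame([0.1, 0.2], [1, 1], cc_family=["A", np.nan])
        with pytest.raises(DomainError):
            subgroup_partition(eff, "cc_family")


@settings(derandomize=True, max_examples=40)
@given(
    data=st.lists(
        st.tuples(
            st.floats(-3, 3, allow_nan=False),
            st.floats(0.1, 4.0, allow_nan=False),
            st.integers(0, 2),
        ),
        min_size=6,
        max_size=40,
    )
)
def test_partition_additivity_property(data):
    """Q_within + Q_between = Q_overall for arbitrary level assignments."""
    import pandas as pd

    labels = [f"g{g}" for _, _, g in data]
    if len(set(labels)) < 2:
        return
    eff = pd.DataFrame(
        {
            "obs_id": [f"o{i}" for i in range(len(data))],
            "es": [e for e, _, _ in data],
            "v": [v for _, v, _ in data],
            "cc_family": labels,
        }
    )
    eff["w_fixed"] = 1.0 / eff["v"]
    tab = subgroup_partition(eff, "cc_family")
    total = tab.total_within[0] + tab.total_between[0]
    assert total == pytest.approx(tab.overall_het.Q, rel=1e-9, abs=1e-9)
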