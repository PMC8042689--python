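"""Kaplan-Meier, log-rank, Cox hazard ratios, tercile grouping."""

import numpy as np
import pandas as pd
import pytest
from itertools import combinations

from splicetransfer.survival import (
    cox_univariate,
    km_curve,
    logrank_test,
    survival_contrast,
    tercile_groups,
    to_years,
)


def test_time_unit_conversion():
    assert to_years([365.25, 730.5], "days").tolist() == [1.0, 2.0]
    assert to_years([1.5], "years").tolist() == [1.5]
    with pytest.raises(ValueError):
        to_years([1.0], "fortnights")


def km_oracle(time, event):
    """Closed-form product-limit estimator by direct risk-set enumeration."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    s, out = 1.0, {}
    for t in sorted(set(time)):
        at_risk = (time >= t).sum()
        d = ((time == t) & (event == 1)).sum()
        s *= 1.0 - d / at_risk
        out[t] = s
    return out


class TestKmCurve:
    def test_all_censored_survival_one(self):
        km = km_curve([1.0, 2.0, 3.0], [0, 0, 0])
        assert (km["survival"] == 1.0).all()

    def test_single_subject_event(self):
        km = km_curve([2.0], [1])
        assert km.loc[km["time"] == 0.0, "survival"].iloc[0] == 1.0
        assert km.loc[km["time"] == 2.0, "survival"].iloc[0] == 0.0

    def test_five_subject_hand_oracle(self):
        """Worked product-limit values: events at 1 and 3, censorings at 2, 4; event at 5.

        S(1) = 4/5, S(3) = 4/5 * 2/3 = 8/15, S(5) = 0.
        """
        time = [1.0, 2.0, 3.0, 4.0, 5.0]
        event = [1, 0, 1, 0, 1]
        km = km_curve(time, event).set_index("time")["survival"]
        assert km.loc[1.0] == pytest.approx(4.0 / 5.0)
        assert km.loc[3.0] == pytest.approx(8.0 / 15.0)
        assert km.loc[5.0] == pytest.approx(0.0)

    def test_matches_enumeration_oracle_random(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = rng.integers(2, 9)
            time = rng.integers(1, 6, size=n).astype(float)
            event = rng.integers(0, 2, size=n)
            if event.sum() == 0:
                continue
            km = km_curve(time, event).set_index("time")["survival"]
            for t, s in km_oracle(time, event).items():
                assert km.loc[t] == pytest.approx(s, abs=1e-12)

    def test_truncation_is_display_only(self):
        time = [1.0, 2.0, 6.0, 8.0]
        event = [1, 1, 1, 0]
        full = km_curve(time, event)
        trunc = km_curve(time, event, truncate_years=5.0)
        assert trunc["time"].max() <= 5.0
        pd.testing.assert_frame_equal(trunc, full[full["time"] <= 5.0].reset_index(drop=True))

    def test_negative_times_rejected(self):
        with pytest.raises(ValueError):
            km_curve([-1.0, 2.0], [1, 0])


class TestLogrank:
    def test_identical_groups_null(self):
        t = [1.0, 2.0, 3.0, 4.0]
        e = [1, 0, 1, 0]
        stat, p = logrank_test(t, e, t, e)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_relabelling_invariance(self):
        rng = np.random.default_rng(1)
        ta, tb = rng.exponential(5, 10), rng.exponential(2, 12)
        ea, eb = np.ones(10, dtype=int), np.ones(12, dtype=int)
        s1, p1 = logrank_test(ta, ea, tb, eb)
        s2, p2 = logrank_test(tb, eb, ta, ea)
        assert s1 == pytest.approx(s2)
        assert p1 == pytest.approx(p2)

    def test_six_subject_permutation_oracle(self):
        """The chi-square p is close to the exact permutation p on a toy set.

        Oracle: enumerate all C(6,3)=20 group assignments of the pooled
        subjects, recompute the log-rank statistic for each, and take the
        fraction with a statistic at least as large.
        """
        time = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        event = np.array([1, 1, 1, 1, 0, 1])
        ga = [0, 1, 2]
        stat_obs, p_obs = logrank_test(time[ga], event[ga], time[[3, 4, 5]], event[[3, 4, 5]])
        stats_perm = []
        for idx in combinations(range(6), 3):
            rest = [i for i in range(6) if i not in idx]
            s, _ = logrank_test(time[list(idx)], event[list(idx)], time[rest], event[rest])
            stats_perm.append(s)
        p_perm = np.mean([s >= stat_obs - 1e-9 for s in stats_perm])
        assert abs(p_obs - p_perm) < 0.25  # chi-square approx on n=6 is crude but close

    def test_clear_separation_significant(self):
        ta = np.linspace(0.1, 1.0, 10)          # all events early
        tb = np.full(10, 10.0)                  # no events
        stat, p = logrank_test(ta, np.ones(10, int), tb, np.zeros(10, int))
        assert p < 0.05

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([1.0], [0], [2.0], [0])


class TestCoxUnivariate:
    def test_null_simulation_unbiased(self):
        """Exchangeable groups: the mean log-HR over simulations is ~0
        (geometric-mean HR within [0.9, 1.1]).  40 simulations at n=80,
        a runtime-scaled version of the 200-seed reference."""
        rng = np.random.default_rng(2)
        log_hrs = []
        for _ in range(40):
            t = rng.exponential(5.0, 80)
            c = rng.uniform(0, 10.0, 80)
            time = np.minimum(t, c)
            event = (t <= c).astype(int)
            group = np.repeat([0, 1], 40)
            res = cox_univariate(time, event, group)
            if not res.degenerate:
                log_hrs.append(np.log(res.hazard_ratio))
        assert 0.9 < np.exp(np.mean(log_hrs)) < 1.1

    def test_planted_hr_recovered(self):
        rng = np.random.default_rng(3)
        lam = np.where(np.repeat([0, 1], 100), 0.4, 0.1)
        t = rng.exponential(1.0 / lam)
        c = rng.uniform(0, 10.0, 200)
        res = cox_univariate(np.minimum(t, c), (t <= c).astype(int), np.repeat([0, 1], 100))
        assert res.ci_low < 4.0 < res.ci_high

    def test_zero_event_group_degenerate(self):
        time = np.array([1.0, 2.0, 3.0, 4.0])
        event = np.array([1, 1, 0, 0])
        group = np.array([0, 0, 1, 1])
        res = cox_univariate(time, event, group)
        assert res.degenerate
        assert res.hazard_ratio == 0.0  # group 1 saw no events

    def test_nonbinary_group_rejected(self):
        with pytest.raises(ValueError):
            cox_univariate([1.0, 2.0], [1, 1], [0, 2])


class TestSurvivalContrast:
    def test_unclassified_excluded(self):
        rng = np.random.default_rng(4)
        n = 60
        table = pd.DataFrame(
            {
                "time": rng.exponential(5, n),
                "event": rng.integers(0, 2, n),
                "group": ["A_like"] * 25 + ["B_like"] * 25 + ["unclassified"] * 10,
            }
        )
        res = survival_contrast(table)
        assert sum(res.n_per_group.values()) == 50
        assert res.truncation_years == 5.0

    def test_missing_group_rejected(self):
        table = pd.DataFrame({"time": [1.0], "event": [1], "group": ["A_like"]})
        with pytest.raises(ValueError):
            survival_contrast(table)


class TestTercileGroups:
    def test_nine_values(self):
        vals = pd.Series(range(1, 10), index=[f"s{i}" for i in range(9)], dtype=float)
        t = tercile_groups(vals)
        assert list(t[vals <= 3].unique()) == ["low"]
        assert list(t[(vals >= 4) & (vals <= 6)].unique()) == ["mid"]
        assert list(t[vals >= 7].unique()) == ["high"]

    def test_ten_values_sizes(self):
        """n=10 distinct values: linear-interpolation terciles with
        boundary-to-lower ties give group sizes {4, 3, 3}."""
        vals = pd.Series(np.arange(1.0, 11.0))
        t = tercile_groups(vals)
        assert t.value_counts().to_dict() == {"low": 4, "mid": 3, "high": 3}

    def test_all_equal_rejected(self):
        with pytest.raises(ValueError):
            tercile_groups(pd.Series([2.0, 2.0, 2.0, 2.0]))

    def test_too_few_rejected(self):
        with pytest.raises(ValueError):
            tercile_groups(pd.Series([1.0, 2.0]))
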