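"""Survival contrasts between molecular subgroups.

Kaplan-Meier product-limit curves, two-group log-rank tests and a
univariate Cox proportional-hazards model for the hazard ratio with its
Wald 95% interval (Efron tie handling, the lifelines default).  Curves
may be truncated for display; statistics always use all the data.
Patients left unclassified by the transfer are excluded from the
A-like/B-like contrast by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

__all__ = [
    "km_curve",
    "logrank_test",
    "cox_univariate",
    "survival_contrast",
    "tercile_groups",
    "to_years",
    "SurvivalContrast",
]

DAYS_PER_YEAR = 365.25


def to_years(time, unit: str = "years"):
    """Convert survival times to the package's canonical unit (years).

    Public registries often record endpoints in days; declare the input
    unit ('years' or 'days') in the configuration and convert once on
    ingest.
    """
    time = np.asarray(time, dtype=float)
    if unit == "years":
        return time
    if unit == "days":
        return time / DAYS_PER_YEAR
    raise ValueError(f"unknown time unit '{unit}'")


@dataclass
class SurvivalContrast:
    """Two-group survival comparison: log-rank test + univariate Cox HR."""

    logrank_statistic: float
    p_value: float
    hazard_ratio: float
    ci_low: float
    ci_high: float
    n_per_group: dict[str, int] = field(default_factory=dict)
    events_per_group: dict[str, int] = field(default_factory=dict)
    degenerate: bool = False
    truncation_years: float | None = None

    def to_dict(self) -> dict:
        return {
            "logrank_statistic": self.logrank_statistic,
            "p_value": self.p_value,
            "hazard_ratio": self.hazard_ratio,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_per_group": self.n_per_group,
            "events_per_group": self.events_per_group,
            "degenerate": self.degenerate,
            "truncation_years": self.truncation_years,
        }


def _check_times(time) -> np.ndarray:
    time = np.asarray(time, dtype=float)
    if (time < 0).any():
        raise ValueError("negative survival times")
    return time


def km_curve(time, event, truncate_years: float | None = None) -> pd.DataFrame:
    """Kaplan-Meier product-limit estimate.

    Returns a step table ``time, survival, n_at_risk, n_events`` (one
    row per distinct observed time, plus t=0).  ``truncate_years`` only
    trims the returned table for plotting; it never affects estimation.
    """
    time = _check_times(time)
    event = np.asarray(event, dtype=int)
    if len(time) == 0:
        raise ValueError("empty survival table")
    kmf = KaplanMeierFitter()
    kmf.fit(time, event)
    et = kmf.event_table
    surv = kmf.survival_function_["KM_estimate"]
    out = pd.DataFrame(
        {
            "time": et.index.to_numpy(dtype=float),
            "survival": surv.reindex(et.index).to_numpy(dtype=float),
            "n_at_risk": et["at_risk"].to_numpy(dtype=int),
            "n_events": et["observed"].to_numpy(dtype=int),
        }
    ).reset_index(drop=True)
    if truncate_years is not None:
        out = out[out["time"] <= truncate_years].reset_index(drop=True)
    return out


def logrank_test(time_a, event_a, time_b, event_b) -> tuple[float, float]:
    """Two-group log-rank chi-square (1 df); returns (statistic, p)."""
    ta, tb = _check_times(time_a), _check_times(time_b)
    ea = np.asarray(event_a, dtype=int)
    eb = np.asarray(event_b, dtype=int)
    if len(ta) == 0 or len(tb) == 0:
        raise ValueError("both groups must be non-empty")
    if ea.sum() + eb.sum() == 0:
        raise ValueError("no events in either group")
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)


def cox_univariate(time, event, group_indicator, ties: str = "efron") -> SurvivalContrast:
    """Univariate Cox PH fit of a binary group covariate.

    ``group_indicator`` is 0/1 (1 = the group whose hazard ratio is
    reported).  Groups with zero events make the partial likelihood
    unbounded; such fits are flagged degenerate with an infinite (or
    zero) hazard-ratio sentinel instead of raising.
    """
    time = _check_times(time)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group_indicator, dtype=int)
    if set(np.unique(group)) - {0, 1}:
        raise ValueError("group_indicator must be binary 0/1")
    n_per = {"0": int((group == 0).sum()), "1": int((group == 1).sum())}
    ev_per = {"0": int(event[group == 0].sum()), "1": int(event[group == 1].sum())}
    if min(n_per.values()) == 0:
        raise ValueError("both groups must be non-empty")

    stat, p = (np.nan, np.nan)
    if event.sum() > 0:
        stat, p = logrank_test(time[group == 0], event[group == 0], time[group == 1], event[group == 1])

    if ev_per["0"] == 0 or ev_per["1"] == 0:
        hr = np.inf if ev_per["0"] == 0 else 0.0
        return SurvivalContrast(stat, p, hr, np.nan, np.nan, n_per, ev_per, degenerate=True)

    df = pd.DataFrame({"time": time, "event": event, "group": group})
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="time", event_col="event")
    except Exception:
        return SurvivalContrast(stat, p, np.nan, np.nan, np.nan, n_per, ev_per, degenerate=True)
    beta = float(cph.params_["group"])
    se = float(cph.standard_errors_["group"])
    return SurvivalContrast(
        logrank_statistic=stat,
        p_value=p,
        hazard_ratio=float(np.exp(beta)),
        ci_low=float(np.exp(beta - 1.959963984540054 * se)),
        ci_high=float(np.exp(beta + 1.959963984540054 * se)),
        n_per_group=n_per,
        events_per_group=ev_per,
    )


def survival_contrast(
    table: pd.DataFrame,
    group_col: str = "group",
    group_a: str = "A_like",
    group_b: str = "B_like",
    time_col: str = "time",
    event_col: str = "event",
    truncation_years: float | None = 5.0,
) -> SurvivalContrast:
    """A-vs-B survival contrast on a tidy table; other groups are dropped.

    The reported hazard ratio is for ``group_b`` relative to
    ``group_a``.  ``truncation_years`` is recorded for plotting only.
    """
    sub = table[table[group_col].isin([group_a, group_b])]
    if sub[group_col].nunique() < 2:
        raise ValueError("one of the contrast groups is absent")
    contrast = cox_univariate(
        sub[time_col], sub[event_col], (sub[group_col] == group_b).astype(int)
    )
    contrast.n_per_group = {group_a: contrast.n_per_group["0"], group_b: contrast.n_per_group["1"]}
    contrast.events_per_group = {
        group_a: contrast.events_per_group["0"], group_b: contrast.events_per_group["1"]
    }
    contrast.truncation_years = truncation_years
    return contrast


def tercile_groups(values: pd.Series) -> pd.Series:
    """Split samples at the empirical 1/3 and 2/3 quantiles into low/mid/high.

    Quantiles use linear interpolation; samples tied with a boundary go
    to the lower group.  Requires >= 3 samples and >= 3 distinct values.
    """
    values = pd.Series(values).astype(float)
    if len(values) < 3:
        raise ValueError("need at least 3 samples for terciles")
    if values.nunique() < 3:
        raise ValueError("need at least 3 distinct values for terciles")
    q1, q2 = np.quantile(values.to_numpy(), [1.0 / 3.0, 2.0 / 3.0], method="linear")
    out = pd.Series(
        np.where(values <= q1, "low", np.where(values <= q2, "mid", "high")),
        index=values.index,
        name="tercile",
    )
    return out
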