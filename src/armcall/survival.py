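"""Kaplan-Meier stratification by aberration flags.

Thin survival support over lifelines: product-limit estimates, the
two-group log-rank test, and stratification of a cohort by an arm-flag
column. Time units are whatever the annotation table carries (the unit
is recorded, never assumed); ties follow the standard risk-set
convention (events precede censorings at equal times).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

from .errors import ValidationError


@dataclass
class KMCurve:
    times: np.ndarray  # event/censoring times, ascending, starting at 0
    survival: np.ndarray  # S(t) immediately after each time
    at_risk: np.ndarray  # risk-set size just before each time
    unit: str = "months"

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "survival": self.survival, "at_risk": self.at_risk})


def km_estimate(times, events, unit: str = "months") -> KMCurve:
    """Product-limit survival estimate. S(0) = 1 and S is non-increasing."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if len(times) == 0:
        raise ValidationError("no survival records")
    if (times < 0).any():
        raise ValidationError("negative survival times")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    grid = kmf.survival_function_.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
    at_risk = kmf.event_table["at_risk"].reindex(grid).to_numpy(dtype=float)
    return KMCurve(times=grid, survival=surv, at_risk=at_risk, unit=unit)


def logrank(times_a, events_a, times_b, events_b) -> tuple[float, float]:
    """Two-group log-rank chi-square (1 df) and its p-value."""
    times_a, times_b = np.asarray(times_a, float), np.asarray(times_b, float)
    events_a, events_b = np.asarray(events_a, int), np.asarray(events_b, int)
    if len(times_a) == 0 or len(times_b) == 0:
        raise ValidationError("both groups must be non-empty")
    if events_a.sum() + events_b.sum() == 0:
        warnings.warn("no events in either group; log-rank p = 1", stacklevel=2)
        return 0.0, 1.0
    res = logrank_test(times_a, times_b, event_observed_A=events_a, event_observed_B=events_b)
    return float(res.test_statistic), float(res.p_value)


def stratify_by_flag(
    flags: pd.DataFrame,
    annotations: pd.DataFrame,
    flag: str,
    endpoint: str = "OS",
    unit: str = "months",
) -> dict:
    """KM curves and log-rank test for samples with vs without a lesion.

    Samples lacking the requested endpoint (for example datasets that
    never recorded event-free survival) are excluded; the exclusion
    count is reported.
    """
    time_col, event_col = {"OS": ("os_time", "os_event"), "EFS": ("efs_time", "efs_event")}[endpoint.upper()]
    if time_col not in annotations.columns:
        raise ValidationError(f"annotations lack {time_col}")
    merged = flags[["sample_id", flag]].merge(annotations, on="sample_id")
    usable = merged.dropna(subset=[time_col, event_col])
    n_excluded = len(merged) - len(usable)
    with_flag = usable[usable[flag].astype(bool)]
    without_flag = usable[~usable[flag].astype(bool)]
    for name, grp in (("with " + flag, with_flag), ("without " + flag, without_flag)):
        if grp.empty:
            raise ValidationError(f"stratum '{name}' is empty")
    stat, p = logrank(
        with_flag[time_col], with_flag[event_col], without_flag[time_col], without_flag[event_col]
    )
    return {
        "flag": flag,
        "endpoint": endpoint.upper(),
        "n_with": len(with_flag),
        "n_without": len(without_flag),
        "n_excluded_missing_survival": n_excluded,
        "km_with": km_estimate(with_flag[time_col], with_flag[event_col], unit),
        "km_without": km_estimate(without_flag[time_col], without_flag[event_col], unit),
        "logrank_statistic": stat,
        "logrank_p": p,
    }
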