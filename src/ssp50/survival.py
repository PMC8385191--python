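"""Kaplan-Meier estimation and log-rank testing stratified by subtype.

Overall survival uses death from any cause as the event; the breast-cancer
composite event (recurrence/metastasis/BC death) is available on request.
Estimation and testing delegate to lifelines; censored subjects at a tied
time remain at risk for events at that time (the standard convention, which
lifelines follows).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from .core import SSP50Error

__all__ = ["SurvivalCurve", "LogRankResult", "km_estimate", "logrank_test", "censoring_summary"]


@dataclass
class SurvivalCurve:
    group: str
    times: np.ndarray  # event-time grid (starts at 0)
    survival: np.ndarray  # product-limit estimates, non-increasing, S(0)=1
    at_risk: np.ndarray  # subjects at risk entering each time
    censor_times: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.survival) > 1e-12):
            raise SSP50Error("survival estimates must be non-increasing")
        if abs(self.survival[0] - 1.0) > 1e-12:
            raise SSP50Error("S(0) must be 1")


@dataclass
class LogRankResult:
    chi_square: float
    degrees_freedom: int
    p_value: float

    def __post_init__(self) -> None:
        if self.degrees_freedom < 1:
            raise SSP50Error("log-rank needs >= 2 groups")
        if not 0.0 <= self.p_value <= 1.0:
            raise SSP50Error("p-value outside [0, 1]")


def _validate(times, events, group_labels):
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    groups = np.asarray(group_labels)
    if not (len(times) == len(events) == len(groups)):
        raise SSP50Error("times, events and group labels must align")
    if times.size == 0:
        raise SSP50Error("empty survival data")
    if np.any(times < 0):
        raise SSP50Error("negative follow-up time")
    return times, events, groups


def km_estimate(times, events, group_labels) -> dict[str, SurvivalCurve]:
    """Product-limit (Kaplan-Meier) survival estimate per group."""
    times, events, groups = _validate(times, events, group_labels)
    curves: dict[str, SurvivalCurve] = {}
    for g in pd.unique(groups):
        mask = groups == g
        if not mask.any():
            raise SSP50Error(f"empty group {g!r}")
        kmf = KaplanMeierFitter()
        kmf.fit(times[mask], events[mask], label=str(g))
        grid = kmf.survival_function_.index.to_numpy(dtype=float)
        surv = kmf.survival_function_[str(g)].to_numpy(dtype=float)
        at_risk = kmf.event_table["at_risk"].to_numpy(dtype=float)
        curves[str(g)] = SurvivalCurve(
            group=str(g),
            times=grid,
            survival=surv,
            at_risk=at_risk,
            censor_times=np.sort(times[mask & ~events]),
        )
    return curves


def logrank_test(times, events, group_labels) -> LogRankResult:
    """k-group log-rank chi-square with k-1 degrees of freedom."""
    times, events, groups = _validate(times, events, group_labels)
    uniq = pd.unique(groups)
    if len(uniq) < 2:
        raise SSP50Error("log-rank needs >= 2 groups")
    if not events.any():
        raise SSP50Error("all subjects censored: log-rank undefined")
    res = multivariate_logrank_test(times, groups, events)
    return LogRankResult(
        chi_square=float(res.test_statistic),
        degrees_freedom=len(uniq) - 1,
        p_value=float(res.p_value),
    )


def censoring_summary(times, events, group_labels) -> dict[str, float]:
    """Per-group fraction of subjects censored (event = False)."""
    _, events, groups = _validate(times, events, group_labels)
    out = {}
    for g in pd.unique(groups):
        mask = groups == g
        out[str(g)] = float((~events[mask]).mean())
    return out


def curves_to_frame(curves: dict[str, SurvivalCurve]) -> pd.DataFrame:
    """Long-format table: group, time, survival, at_risk."""
    rows = []
    for g, c in curves.items():
        for t, s, r in zip(c.times, c.survival, c.at_risk):
            rows.append({"group": g, "time": t, "survival": s, "at_risk": r})
    return pd.DataFrame(rows)
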