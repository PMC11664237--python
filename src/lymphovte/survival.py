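"""Kaplan-Meier estimation and log-rank comparison for overall survival.

Used to contrast survival of patients who developed a VTE against those who
did not.  Estimation is delegated to lifelines; this module fixes the
conventions (deaths before censorings at tied times, right-continuous step
evaluation) and exposes a plain-array curve object that serialises to CSV.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test


@dataclass(frozen=True)
class SurvivalCurve:
    """Product-limit curve on an event-time grid (months).

    ``times`` starts at 0 with ``survival[0] == 1``; ``at_risk`` is the
    risk-set size just before each time; ``censor_times`` are the censored
    follow-up times (no step, risk set only).
    """

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    censor_times: np.ndarray

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"time": self.times, "survival": self.survival, "at_risk": self.at_risk}
        )


def kaplan_meier(times: Sequence[float], events: Sequence[bool]) -> SurvivalCurve:
    """Product-limit survival estimate.

    ``events[i]`` True means subject *i* died at ``times[i]``; False means
    censored then.  Censored subjects leave the risk set without a step.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if len(t) == 0:
        raise ValueError("empty input")
    if len(t) != len(e):
        raise ValueError("times and events must have equal length")
    if (t < 0).any():
        raise ValueError("negative times")

    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    sf = kmf.survival_function_
    grid = sf.index.to_numpy(dtype=float)
    surv = sf.iloc[:, 0].to_numpy(dtype=float)
    if grid[0] != 0.0:
        grid = np.concatenate(([0.0], grid))
        surv = np.concatenate(([1.0], surv))
    at_risk = np.array([(t >= u).sum() for u in grid])
    return SurvivalCurve(
        times=grid, survival=surv, at_risk=at_risk, censor_times=np.sort(t[~e])
    )


def survival_at(curve: SurvivalCurve, horizon: float) -> float:
    """Right-continuous step evaluation S(horizon).

    Beyond the last observed time the last value is carried forward with an
    extrapolation warning.
    """
    if horizon < 0:
        raise ValueError("horizon must be non-negative")
    if horizon > curve.times[-1]:
        warnings.warn(
            f"horizon {horizon:g} exceeds last observed time "
            f"{curve.times[-1]:g}; returning the last estimate",
            stacklevel=2,
        )
        return float(curve.survival[-1])
    idx = np.searchsorted(curve.times, horizon, side="right") - 1
    return float(curve.survival[idx])


def log_rank(
    times_a: Sequence[float],
    events_a: Sequence[bool],
    times_b: Sequence[float],
    events_b: Sequence[bool],
) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p-value)."""
    ta, tb = np.asarray(times_a, float), np.asarray(times_b, float)
    ea, eb = np.asarray(events_a, bool), np.asarray(events_b, bool)
    if len(ta) == 0 or len(tb) == 0:
        raise ValueError("both groups must be non-empty")
    if not (ea.any() or eb.any()):
        raise ValueError("no events in either group: log-rank undefined")
    res = logrank_test(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)
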