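"""Kaplan–Meier estimation and log-rank comparison of predicted PFS groups.

The validation step of the pipeline groups patients by their *predicted*
High/Low PFS label and asks whether the groups' *actual* progression-free
survival differs: product-limit survival curves per group and a two-group
log-rank test (chi-square, 1 degree of freedom).  Estimation and testing are
delegated to lifelines; this module shapes inputs/outputs to the pipeline's
types and conventions (events precede censorings at tied times, the event
flag defaults to observed when absent).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .cohort import HIGH, LOW
from .reference import ClinicalRecord

logger = logging.getLogger(__name__)

ALPHA = 0.05


@dataclass(frozen=True)
class KMCurve:
    """Product-limit estimate: S(t) tabulated at the distinct event times."""

    event_times: tuple[float, ...]
    n_at_risk: tuple[int, ...]
    n_events: tuple[int, ...]
    survival: tuple[float, ...]
    censoring_times: tuple[float, ...]

    def survival_at(self, t: float) -> float:
        s = 1.0
        for ti, si in zip(self.event_times, self.survival):
            if ti <= t:
                s = si
            else:
                break
        return s

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.event_times,
                "n_at_risk": self.n_at_risk,
                "n_events": self.n_events,
                "survival": self.survival,
            }
        )


@dataclass(frozen=True)
class LogRankResult:
    statistic: float
    p_value: float
    degrees_of_freedom: int = 1
    evaluable: bool = True


def km_estimate(times: Sequence[float], events: Sequence[bool]) -> KMCurve:
    """Kaplan–Meier product-limit estimator.

    ``events[i]`` True marks an observed progression at ``times[i]``; False
    marks censoring.  At tied times events are processed before censorings.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise ValueError("empty input")
    if np.any(times < 0):
        raise ValueError("times must be non-negative")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    table = kmf.event_table
    event_rows = table[table["observed"] > 0]
    surv = [float(kmf.survival_function_at_times(t).iloc[0]) for t in event_rows.index]
    return KMCurve(
        event_times=tuple(float(t) for t in event_rows.index),
        n_at_risk=tuple(int(x) for x in event_rows["at_risk"]),
        n_events=tuple(int(x) for x in event_rows["observed"]),
        survival=tuple(surv),
        censoring_times=tuple(float(t) for t in times[~events]),
    )


def logrank_test(
    times_a: Sequence[float],
    events_a: Sequence[bool],
    times_b: Sequence[float],
    events_b: Sequence[bool],
) -> LogRankResult:
    """Two-group log-rank test; chi-square p-value with 1 df."""
    if len(times_a) == 0 or len(times_b) == 0:
        raise ValueError("both groups must be non-empty")
    if not (any(events_a) or any(events_b)):
        logger.warning("no events in either group; log-rank statistic is 0")
        return LogRankResult(statistic=0.0, p_value=1.0)
    res = _ll_logrank(
        np.asarray(times_a, dtype=float),
        np.asarray(times_b, dtype=float),
        event_observed_A=np.asarray(events_a, dtype=bool),
        event_observed_B=np.asarray(events_b, dtype=bool),
    )
    return LogRankResult(statistic=float(res.test_statistic), p_value=float(res.p_value))


def validate_predictions(
    predictions: Mapping[str, str],
    records: Mapping[str, ClinicalRecord],
    alpha: float = ALPHA,
) -> tuple[dict[str, KMCurve], LogRankResult, bool]:
    """KM curves on actual PFS for predicted High vs predicted Low groups.

    Returns ({label: KMCurve}, log-rank result, significant-at-alpha flag).
    A prediction set with an empty group is flagged non-evaluable.
    """
    missing = [p for p in predictions if p not in records]
    if missing:
        raise ValueError(f"no clinical record for predicted patient(s): {missing[:5]}")
    groups: dict[str, tuple[list[float], list[bool]]] = {HIGH: ([], []), LOW: ([], [])}
    for pid, label in predictions.items():
        rec = records[pid]
        groups[label][0].append(rec.pfs_months)
        groups[label][1].append(rec.event)
    if not groups[HIGH][0] or not groups[LOW][0]:
        logger.warning("one predicted group is empty; survival validation not evaluable")
        return {}, LogRankResult(0.0, 1.0, evaluable=False), False
    curves = {label: km_estimate(t, e) for label, (t, e) in groups.items()}
    result = logrank_test(*groups[HIGH], *groups[LOW])
    return curves, result, result.p_value < alpha
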