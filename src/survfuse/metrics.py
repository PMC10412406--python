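"""Survival evaluation: concordance index, cumulative event-time AUC,
median-risk stratification, log-rank test and Kaplan-Meier curves.

The concordance index is the fraction of comparable patient pairs whose
predicted risks order the observed times correctly; a pair is comparable when
the earlier time belongs to an observed event (a pair is dropped when the
earlier time is censored or both members are censored). The cumulative AUC
averages, over every distinct event time t, the correct orderings between
patients who had their event before t and patients still at risk after t.
Risk ties count 1/2 in both metrics (Harrell convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .data import SurvivalOutcome

__all__ = [
    "concordance_index",
    "cumulative_auc",
    "stratify_by_median",
    "logrank_test",
    "km_curve",
]


def _unpack(outcome) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(outcome, SurvivalOutcome):
        return outcome.time, outcome.event
    time, event = outcome
    return np.asarray(time, dtype=float), np.asarray(event).astype(int)


def concordance_index(risk: np.ndarray, outcome) -> float:
    """Harrell's C over comparable pairs (earlier member has the event).

    For a pair with O_i < O_j and event_i = 1: 1 if risk_i > risk_j, 1/2 if
    tied, 0 otherwise. Raises when no pair is comparable.
    """
    risk = np.asarray(risk, dtype=float)
    time, event = _unpack(outcome)
    earlier = (time[:, None] < time[None, :]) & (event[:, None] == 1)
    n_pairs = int(earlier.sum())
    if n_pairs == 0:
        raise ValueError("no comparable pairs (need an observed event before another time)")
    higher = risk[:, None] > risk[None, :]
    tied = risk[:, None] == risk[None, :]
    score = (earlier & higher).sum() + 0.5 * (earlier & tied).sum()
    return float(score / n_pairs)


def cumulative_auc(risk: np.ndarray, outcome) -> float:
    """Event-time-cumulative AUC.

    For each distinct event time t: cases are patients with an observed event
    strictly before t, controls are patients with O_j > t; the score counts
    risk_case > risk_control (ties 1/2) and divides by the total number of
    (case, control, t) triples.
    """
    risk = np.asarray(risk, dtype=float)
    time, event = _unpack(outcome)
    event_times = np.unique(time[event == 1])
    num = 0
    hits = 0.0
    for t in event_times:
        cases = (time < t) & (event == 1)
        controls = time > t
        n_c, n_k = int(cases.sum()), int(controls.sum())
        if n_c == 0 or n_k == 0:
            continue
        rc = risk[cases][:, None]
        rk = risk[controls][None, :]
        hits += (rc > rk).sum() + 0.5 * (rc == rk).sum()
        num += n_c * n_k
    if num == 0:
        raise ValueError("no comparable (case, control) pair at any event time")
    return float(hits / num)


def stratify_by_median(risk: np.ndarray) -> np.ndarray:
    """Labels ``"high"`` (risk > median) / ``"low"`` (risk <= median)."""
    risk = np.asarray(risk, dtype=float)
    if risk.size < 2:
        raise ValueError("need at least two samples to stratify")
    if np.all(risk == risk[0]):
        raise ValueError("constant risk scores cannot be stratified")
    med = float(np.median(risk))
    return np.where(risk > med, "high", "low")


def logrank_test(groups: np.ndarray, outcome) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p-value)."""
    time, event = _unpack(outcome)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if labels.size != 2:
        raise ValueError(f"expected exactly two nonempty groups, got {labels.tolist()}")
    g0 = groups == labels[0]
    if event.sum() == 0:
        raise ValueError("log-rank test requires at least one observed event")
    res = _ll_logrank(time[g0], time[~g0], event_observed_A=event[g0], event_observed_B=event[~g0])
    return float(res.test_statistic), float(res.p_value)


@dataclass
class KMCurve:
    """Product-limit survival curve as a right-continuous step function."""

    times: np.ndarray
    survival: np.ndarray

    def at(self, t: np.ndarray | float) -> np.ndarray:
        idx = np.searchsorted(self.times, np.atleast_1d(t), side="right") - 1
        return self.survival[np.maximum(idx, 0)]


def km_curve(outcome, group: np.ndarray | None = None) -> KMCurve:
    """Kaplan-Meier estimate for one (sub)group; drops only at event times."""
    time, event = _unpack(outcome)
    if group is not None:
        group = np.asarray(group, dtype=bool)
        if not group.any():
            raise ValueError("empty group")
        time, event = time[group], event[group]
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    sf = kmf.survival_function_
    return KMCurve(times=sf.index.to_numpy(dtype=float), survival=sf.iloc[:, 0].to_numpy())
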