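"""Kaplan-Meier estimation, restricted mean survival and log-rank tests.

Overall survival is analysed per modified BG score (0-3) and per risk
category. "Mean survival" is the Kaplan-Meier restricted mean: the area under
the product-limit curve up to a horizon, by default the largest observed time
in the group — the convention behind the group means printed by standard
statistical packages. Estimation and testing are backed by lifelines;
censored subjects tied with events at t remain at risk for those events.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test, multivariate_logrank_test
from lifelines.utils import restricted_mean_survival_time

from .stats import AssociationResult

__all__ = [
    "KMCurve",
    "km_estimate",
    "restricted_mean_survival",
    "log_rank",
    "pairwise_log_rank",
]


@dataclass(frozen=True)
class KMCurve:
    """Stepwise product-limit estimate with at-risk accounting.

    ``event_times`` are the distinct times with at least one event, ascending;
    ``survival_prob[i]`` is S(t) just after ``event_times[i]``.
    """

    event_times: np.ndarray
    survival_prob: np.ndarray
    n_at_risk: np.ndarray
    n_events: np.ndarray
    max_observed_time: float

    def survival_at(self, t: float) -> float:
        """S(t) by right-continuous step interpolation."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival_prob[idx])


def km_estimate(times: Sequence[float], events: Sequence[int]) -> KMCurve:
    """Product-limit estimator S(t) = prod(1 - d_i/n_i) over event times <= t."""
    t = np.asarray(times, float)
    e = np.asarray(events, int)
    if t.size == 0:
        raise ValueError("empty survival input")
    if t.shape != e.shape:
        raise ValueError("times and events must have equal length")
    if (t < 0).any():
        raise ValueError("negative survival times")
    kmf = KaplanMeierFitter().fit(t, e)
    tbl = kmf.event_table
    has_event = tbl["observed"] > 0
    ev_times = tbl.index.values[has_event].astype(float)
    surv = kmf.survival_function_at_times(ev_times).to_numpy()
    return KMCurve(
        event_times=ev_times,
        survival_prob=surv,
        n_at_risk=tbl["at_risk"].to_numpy()[has_event],
        n_events=tbl["observed"].to_numpy()[has_event],
        max_observed_time=float(t.max()),
    )


def restricted_mean_survival(
    times: Sequence[float],
    events: Sequence[int],
    horizon: float | None = None,
) -> float:
    """Area under the KM curve from 0 to ``horizon`` (months).

    Default horizon is the largest observed time in the group. The horizon may
    not exceed the largest observed time (the curve is undefined beyond it).
    """
    t = np.asarray(times, float)
    e = np.asarray(events, int)
    if t.size == 0:
        raise ValueError("empty survival input")
    t_max = float(t.max())
    if horizon is None:
        horizon = t_max
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    if horizon > t_max + 1e-12:
        raise ValueError(
            f"horizon {horizon} exceeds largest observed time {t_max}"
        )
    kmf = KaplanMeierFitter().fit(t, e)
    return float(restricted_mean_survival_time(kmf, t=horizon))


def _clean_groups(
    groups: Mapping[str, tuple[Sequence[float], Sequence[int]]],
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    out = {}
    for label, (t, e) in groups.items():
        t = np.asarray(t, float)
        e = np.asarray(e, int)
        if t.size == 0:
            warnings.warn(f"dropping empty group {label!r}", stacklevel=3)
            continue
        out[str(label)] = (t, e)
    if len(out) < 2:
        raise ValueError("need at least 2 non-empty groups")
    return out


def log_rank(
    groups: Mapping[str, tuple[Sequence[float], Sequence[int]]],
) -> AssociationResult:
    """k-sample log-rank chi-square test on (time, event) groups; df = k - 1."""
    g = _clean_groups(groups)
    t = np.concatenate([v[0] for v in g.values()])
    e = np.concatenate([v[1] for v in g.values()])
    lab = np.concatenate([[k] * len(v[0]) for k, v in g.items()])
    res = multivariate_logrank_test(t, lab, e)
    return AssociationResult(
        "log_rank", float(res.test_statistic), len(g) - 1, float(res.p_value)
    )


def pairwise_log_rank(
    groups: Mapping[str, tuple[Sequence[float], Sequence[int]]],
) -> pd.DataFrame:
    """Matrix of unadjusted pairwise log-rank p-values between groups."""
    g = _clean_groups(groups)
    labels = list(g)
    p = pd.DataFrame(np.nan, index=labels, columns=labels)
    for a, b in combinations(labels, 2):
        res = logrank_test(g[a][0], g[b][0], g[a][1], g[b][1])
        p.loc[a, b] = p.loc[b, a] = float(res.p_value)
    np.fill_diagonal(p.values, 1.0)
    return p
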