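"""Cohort-level statistics: expression categorization, group tests, survival.

Expression of a validation gene is categorized against healthy donors as
up/down/normal using two thresholds applied conjunctively (default: more than
2-fold AND more than one order of magnitude from the healthy mean, so 10-fold
is the effective cutoff).  Category frequencies across risk groups are
compared with Fisher's exact test, continuous methylation differences with
two-tailed Mann-Whitney tests, and outcomes with Kaplan-Meier curves, the
two-sided log-rank test, and Aalen-Johansen cumulative incidence of relapse
with death as a competing risk.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import AalenJohansenFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

UP = "up"
DOWN = "down"
NORMAL = "normal"


@dataclass(frozen=True)
class Contingency2x2:
    """2x2 table; rows are groups, columns outcome yes/no."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")


def classify_expression(
    value: float,
    healthy_values: Sequence[float],
    fold_min: float = 2.0,
    magnitude_min: float = 10.0,
) -> str:
    """Categorize one expression value against the healthy-donor mean.

    'up' when value exceeds the healthy mean by more than both thresholds
    (conjunctive, so max(fold_min, magnitude_min)-fold), 'down' for the
    mirror-image deficit, 'normal' otherwise.
    """
    healthy = np.asarray(healthy_values, float)
    if healthy.size == 0 or (healthy <= 0).any():
        raise ValueError("healthy_values must be non-empty and positive")
    if value <= 0:
        raise ValueError("expression value must be positive")
    h = healthy.mean()
    cutoff = max(fold_min, magnitude_min)
    if value / h > cutoff:
        return UP
    if h / value > cutoff:
        return DOWN
    return NORMAL


def fisher_exact(table: Contingency2x2) -> float:
    """Two-sided Fisher's exact p: sum of hypergeometric probabilities of
    tables (at fixed margins) no more likely than the observed one."""
    _, p = stats.fisher_exact([[table.a, table.b], [table.c, table.d]], alternative="two-sided")
    return float(p)


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Mann-Whitney U (for x) and two-sided p.

    Exact enumeration when min(n, m) <= 8 and the pooled data are tie-free;
    otherwise the normal approximation with tie correction (no continuity
    correction, so identical samples give p = 1 exactly).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    tie_free = np.unique(pooled).size == pooled.size
    if min(x.size, y.size) <= 8 and tie_free:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        res = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=False
        )
    return float(res.statistic), float(min(res.pvalue, 1.0))


@dataclass
class StepFunction:
    """Right-continuous step function: value(t) = values[i] for the largest
    times[i] <= t, and ``initial`` before the first time."""

    times: np.ndarray
    values: np.ndarray
    initial: float

    def __call__(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return float(self.values[idx]) if idx >= 0 else self.initial


def kaplan_meier(times: Sequence[float], events: Sequence[int]) -> StepFunction:
    """Product-limit survival estimate under right censoring.

    Starts at 1 and is non-increasing; with no events it stays flat at 1.
    """
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    sf = kmf.survival_function_
    return StepFunction(
        times=sf.index.to_numpy(float), values=sf.iloc[:, 0].to_numpy(float), initial=1.0
    )


def logrank_test(
    times_a: Sequence[float],
    events_a: Sequence[int],
    times_b: Sequence[float],
    events_b: Sequence[int],
) -> tuple[float, float]:
    """Two-sided log-rank chi-square statistic (1 df) and p.

    Undefined (ValueError) when neither group has any event.
    """
    ea = np.asarray(events_a, int)
    eb = np.asarray(events_b, int)
    if ea.size == 0 or eb.size == 0:
        raise ValueError("both groups must be non-empty")
    if ea.sum() + eb.sum() == 0:
        raise ValueError("log-rank undefined: no events in either group")
    res = _ll_logrank(times_a, times_b, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)


def relapse_incidence(
    times: Sequence[float],
    relapse_events: Sequence[int],
    death_events: Sequence[int],
) -> StepFunction:
    """Aalen-Johansen cumulative incidence of relapse with death (without
    relapse) as the competing risk.

    Event flags must be mutually exclusive per sample; a sample with neither
    flag is censored.  The estimate is non-decreasing and bounded by 1; with
    no deaths it reduces to 1 - KM of relapse.
    """
    times = np.asarray(times, float)
    rel = np.asarray(relapse_events, int)
    dth = np.asarray(death_events, int)
    if ((rel == 1) & (dth == 1)).any():
        raise ValueError("relapse and death flags must be mutually exclusive")
    event_type = np.where(rel == 1, 1, np.where(dth == 1, 2, 0))
    if (event_type == 1).sum() == 0:
        grid = np.unique(times)
        return StepFunction(times=grid, values=np.zeros_like(grid, float), initial=0.0)
    ajf = AalenJohansenFitter(calculate_variance=False)
    ajf.fit(times, event_type, event_of_interest=1)
    ci = ajf.cumulative_density_
    return StepFunction(
        times=ci.index.to_numpy(float), values=ci.iloc[:, 0].to_numpy(float), initial=0.0
    )


def compare_groups_mannwhitney(
    values: pd.Series, groups: pd.Series, group_a: str, group_b: str
) -> dict:
    """Convenience wrapper returning a JSON-ready test record."""
    x = values[groups == group_a].dropna().to_numpy(float)
    y = values[groups == group_b].dropna().to_numpy(float)
    u, p = mann_whitney(x, y)
    return {
        "test": "mann_whitney",
        "group_a": group_a,
        "group_b": group_b,
        "n_a": int(x.size),
        "n_b": int(y.size),
        "U": u,
        "p": p,
    }


def km_plot(ax, fitted: StepFunction, label: str | None = None, **kwargs):
    """Plot a survival/incidence step function on a matplotlib axis."""
    t = np.concatenate([[0.0], fitted.times])
    v = np.concatenate([[fitted.initial], fitted.values])
    ax.step(t, v, where="post", label=label, **kwargs)
    return ax
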