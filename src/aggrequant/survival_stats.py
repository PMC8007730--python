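"""Survival curves from bleb/burst event times and the group-comparison tests
used for reporting.

Membrane bursting of a neuron under time-lapse observation is treated as
its death event; cells still intact when imaging stops are right-censored.
The survival curve is the product-limit (Kaplan-Meier) estimate, which with
no censoring reduces to the empirical survival function.

Reporting tests: two-sided Mann-Whitney (exact enumeration for small
samples), two-sided Fisher's exact, and one-way ANOVA with Bonferroni
pairwise comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb, sqrt
from pathlib import Path

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats

__all__ = [
    "EventTable",
    "SurvivalCurve",
    "km_estimate",
    "mann_whitney_u",
    "fisher_exact",
    "anova_bonferroni",
]


@dataclass
class EventTable:
    """Per-subject event times: burst observed (event=1) or censored (event=0)."""

    subject: np.ndarray
    group: np.ndarray
    time_min: np.ndarray
    event: np.ndarray

    def __post_init__(self) -> None:
        self.subject = np.asarray(self.subject)
        self.group = np.asarray(self.group)
        self.time_min = np.asarray(self.time_min, dtype=np.float64)
        self.event = np.asarray(self.event, dtype=np.int64)
        n = len(self.subject)
        if not (len(self.group) == len(self.time_min) == len(self.event) == n):
            raise ValueError("columns must have equal length")
        if np.any(self.time_min <= 0):
            raise ValueError("event/censor times must be > 0")
        if not np.all(np.isin(self.event, (0, 1))):
            raise ValueError("event flags must be 0 or 1")

    def groups(self) -> list[str]:
        return sorted({str(g) for g in self.group})

    def subset(self, group: str) -> "EventTable":
        sel = self.group.astype(str) == group
        return EventTable(self.subject[sel], self.group[sel], self.time_min[sel], self.event[sel])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"subject": self.subject, "group": self.group,
             "time_min": self.time_min, "event": self.event}
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "EventTable":
        df = pd.read_csv(path)
        return cls(df["subject"].to_numpy(), df["group"].to_numpy(),
                   df["time_min"].to_numpy(), df["event"].to_numpy())


@dataclass
class SurvivalCurve:
    """Right-continuous step estimate of the surviving fraction."""

    group: str
    times: np.ndarray          # distinct event/censor times, ascending
    survival: np.ndarray       # S(t) just after each time
    at_risk: np.ndarray        # risk-set size just before each time
    n_subjects: int

    def s_at(self, t: float) -> float:
        """S(t); 1 before the first observed time."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    @property
    def median_time(self) -> float:
        """Smallest t with S(t) <= 0.5, or NaN if the curve never falls that far."""
        below = np.nonzero(self.survival <= 0.5)[0]
        return float(self.times[below[0]]) if len(below) else float("nan")


def km_estimate(events: EventTable, group: str | None = None) -> SurvivalCurve:
    """Product-limit survival estimate for one group (or the whole table).

    Censored subjects leave the risk set without causing a drop.
    """
    sub = events if group is None else events.subset(group)
    if len(sub.time_min) == 0:
        raise ValueError(f"no subjects in group {group!r}")
    kmf = KaplanMeierFitter()
    kmf.fit(sub.time_min, event_observed=sub.event)
    # lifelines includes t=0 as the leading row; drop it so `times` are observed times
    sf = kmf.survival_function_
    times = sf.index.to_numpy(dtype=float)
    surv = sf.iloc[:, 0].to_numpy(dtype=float)
    keep = times > 0
    at_risk = kmf.event_table["at_risk"].to_numpy(dtype=float)[keep]
    return SurvivalCurve(
        group=group if group is not None else "",
        times=times[keep],
        survival=surv[keep],
        at_risk=at_risk,
        n_subjects=len(sub.time_min),
    )


def mann_whitney_u(a, b) -> float:
    """Two-sided Mann-Whitney p-value.

    Exact enumeration when the combined sample has no ties and n_a + n_b
    <= 12; otherwise the normal approximation with tie correction and
    continuity correction. Identical rank sums (no separation at all)
    report p = 1.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    combined = np.concatenate([a, b])
    has_ties = len(np.unique(combined)) < combined.size
    u = float(stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").statistic)
    if u == a.size * b.size / 2.0:
        return 1.0  # U at its null mean: no evidence of separation
    if not has_ties and a.size + b.size <= 12:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return min(1.0, float(res.pvalue))


def fisher_exact(table) -> float:
    """Two-sided Fisher's exact p for a 2x2 count table.

    Standard rule: sum of hypergeometric probabilities of tables (with the
    observed margins) no more probable than the observed one. A zero margin
    leaves a degenerate distribution; p = 1 by convention.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("need a 2x2 table of nonnegative counts")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        return 1.0
    return float(stats.fisher_exact(t, alternative="two-sided").pvalue)


@dataclass
class AnovaResult:
    f_statistic: float
    p_value: float
    pairwise: dict[tuple[int, int], float]  # (i, j) -> Bonferroni-adjusted p


def anova_bonferroni(groups: list) -> AnovaResult:
    """One-way ANOVA F test plus Bonferroni-adjusted pairwise comparisons.

    Pairwise tests are t tests on the pooled within-group variance
    (residual df = N - k); each raw p is multiplied by the number of pairs
    and capped at 1. All-identical data give F = 0 and p = 1.
    """
    groups = [np.asarray(g, dtype=np.float64) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(g.size < 2 for g in groups):
        raise ValueError("each group needs >= 2 observations")
    all_vals = np.concatenate(groups)
    n_pairs = comb(len(groups), 2)
    if np.ptp(all_vals) == 0:
        pairwise = {pair: 1.0 for pair in combinations(range(len(groups)), 2)}
        return AnovaResult(0.0, 1.0, pairwise)
    f_res = stats.f_oneway(*groups)
    n_total = all_vals.size
    k = len(groups)
    df_resid = n_total - k
    mse = sum(((g - g.mean()) ** 2).sum() for g in groups) / df_resid
    pairwise = {}
    for i, j in combinations(range(k), 2):
        gi, gj = groups[i], groups[j]
        se = sqrt(mse * (1 / gi.size + 1 / gj.size))
        if se == 0:
            p_raw = 1.0
        else:
            t_stat = (gi.mean() - gj.mean()) / se
            p_raw = 2 * stats.t.sf(abs(t_stat), df_resid)
        pairwise[(i, j)] = min(1.0, p_raw * n_pairs)
    return AnovaResult(float(f_res.statistic), float(f_res.pvalue), pairwise)
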