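"""Kaplan-Meier estimation, log-rank comparison and median-split strata.

Thin layer over lifelines: the product-limit estimator and Mantel-Haenszel
log-rank test are standard, so the established implementations back the
module surface.  Median dichotomization puts samples strictly above the
median in the high group; ties at the median go to the low group, a
deterministic policy that is logged on the returned object.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

from .core_io import SurvivalRecord
from .errors import ValidationError


@dataclass
class KmCurve:
    """Kaplan-Meier step function: event times, at-risk counts, S(t)."""

    times: np.ndarray        # distinct observed times, ascending
    at_risk: np.ndarray      # subjects at risk just before each time
    survival: np.ndarray     # product-limit estimate at each time
    n_subjects: int
    n_events: int

    def probability_at(self, t: float) -> float:
        """S(t): survival probability at time t (right-continuous step)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def _arrays(records: Sequence[SurvivalRecord]):
    times = np.array([r.time for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=int)
    if np.any(times < 0):
        raise ValidationError("negative follow-up time")
    return times, events


def km_estimate(records: Sequence[SurvivalRecord]) -> KmCurve:
    """Product-limit survival curve; censored-only times do not drop it."""
    if not records:
        raise ValidationError("need at least one record")
    times, events = _arrays(records)
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    surv = kmf.survival_function_["KM_estimate"]
    # align on the fitter's timeline, excluding the synthetic t=0 row
    observed = set(times.tolist())
    timeline = np.array([t for t in kmf.event_table.index if t in observed])
    at_risk = kmf.event_table.loc[timeline, "at_risk"].to_numpy(dtype=float)
    survival = np.array([float(surv.loc[t]) for t in timeline])
    return KmCurve(times=timeline, at_risk=at_risk, survival=survival,
                   n_subjects=len(records), n_events=int(events.sum()))


def logrank(a: Sequence[SurvivalRecord],
            b: Sequence[SurvivalRecord]) -> tuple[float, float]:
    """Mantel-Haenszel log-rank test: (chi-square, two-sided p)."""
    if not a or not b:
        raise ValidationError("both groups must be non-empty")
    ta, ea = _arrays(a)
    tb, eb = _arrays(b)
    if ea.sum() + eb.sum() == 0:
        warnings.warn("zero events in both groups; log-rank undefined",
                      UserWarning, stacklevel=2)
        return 0.0, 1.0
    res = logrank_test(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)


@dataclass
class MedianSplit:
    """Outcome of a median dichotomization plus log-rank comparison."""

    high: list
    low: list
    cutpoint: float
    tie_policy: str
    chi_square: float
    p_value: float


def median_split(expression: Mapping[str, float],
                 records: Sequence[SurvivalRecord]) -> MedianSplit:
    """Stratify subjects by a feature's abundance at the cohort median.

    Only samples present in both inputs are used.  High = strictly above
    the median of the used samples; ties at the median fall to the low
    group.  The grouping is invariant under monotone transforms of the
    expression values.
    """
    usable = [r for r in records if r.sample in expression
              and not np.isnan(expression[r.sample])]
    if not usable:
        raise ValidationError("no shared samples between expression and "
                              "survival records")
    values = np.array([expression[r.sample] for r in usable], dtype=float)
    if np.all(values == values[0]):
        raise ValidationError("all expression values identical; "
                              "no split possible")
    cut = float(np.median(values))
    high = [r for r, v in zip(usable, values) if v > cut]
    low = [r for r, v in zip(usable, values) if v <= cut]
    chi2, p = logrank(high, low)
    return MedianSplit(high=high, low=low, cutpoint=cut,
                       tie_policy="ties-at-median -> low", chi_square=chi2,
                       p_value=p)
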