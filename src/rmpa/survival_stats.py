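"""Kaplan-Meier estimation and log-rank comparison between RMPA subtypes.

Thin, validated wrappers over lifelines: the product-limit estimator for
overall survival and the standard two-group log-rank test (hypergeometric
variance at tied event times, chi-square(1) p-value), plus a per-grade
stratified comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from .data_io import ClinicalTable


@dataclass
class SurvivalCurve:
    """Product-limit estimate: step values at the observed event times."""

    event_times: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    survival: np.ndarray
    median: float = np.nan

    def probability_at(self, t: float) -> float:
        """S(t): survival probability just after time t."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class LogRankResult:
    statistic: float
    p_value: float
    observed: dict
    expected: dict
    df: int = 1


def _validate(times, events):
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=float)
    if times.size == 0:
        raise ValueError("no subjects")
    if np.any(times <= 0):
        raise ValueError("survival times must be positive")
    if not np.isin(events, [0, 1]).all():
        raise ValueError("event indicators must be 0 or 1")
    return times, events.astype(int)


def km_estimate(times, events) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimator of overall survival.

    Subjects censored at an event time are counted at risk at that time
    (standard convention).
    """
    times, events = _validate(times, events)
    kmf = KaplanMeierFitter().fit(times, events)
    tbl = kmf.event_table
    at_event = tbl[tbl["observed"] > 0]
    event_times = at_event.index.to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(event_times).to_numpy()
    return SurvivalCurve(
        event_times=event_times,
        at_risk=at_event["at_risk"].to_numpy(dtype=int),
        n_events=at_event["observed"].to_numpy(dtype=int),
        survival=surv,
        median=float(kmf.median_survival_time_),
    )


def logrank_test(times, events, groups) -> LogRankResult:
    """Two-group log-rank test with tied deaths in one hypergeometric term."""
    times, events = _validate(times, events)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) != 2:
        raise ValueError(f"exactly 2 groups required, got {len(labels)}")
    for lab in labels:
        if (groups == lab).sum() == 0:
            raise ValueError(f"group {lab!r} is empty")
    if events.sum() == 0:
        raise ValueError("no events observed in either group")
    res = multivariate_logrank_test(times, groups, events)
    observed, expected = _observed_expected(times, events, groups, labels)
    return LogRankResult(
        statistic=float(res.test_statistic),
        p_value=float(res.p_value),
        observed=observed,
        expected=expected,
    )


def _observed_expected(times, events, groups, labels):
    """Per-group observed and expected event counts (sums match)."""
    observed = {lab: float(events[groups == lab].sum()) for lab in labels}
    expected = {lab: 0.0 for lab in labels}
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        d = float(((times == t) & (events == 1)).sum())
        n = float(at_risk.sum())
        for lab in labels:
            expected[lab] += d * at_risk[groups == lab].sum() / n
    return observed, expected


def stratified_compare(
    clinical: ClinicalTable,
    labels: pd.Series,
    stratum: str = "grade",
) -> pd.DataFrame:
    """Log-rank within each stratum; strata lacking >=2 subjects per group
    are reported "insufficient"."""
    if stratum not in clinical.data.columns:
        raise ValueError(f"unknown stratum variable {stratum!r}")
    merged = clinical.data.join(labels.rename("label"), how="inner")
    merged = merged[clinical.usable_for_survival.reindex(merged.index, fill_value=False)]
    merged = merged[merged["label"].notna()]
    rows = []
    for value, sub in merged.groupby(stratum, observed=True, dropna=False):
        counts = sub["label"].value_counts()
        if len(counts) < 2 or counts.min() < 2:
            rows.append(
                {"stratum": value, "n": len(sub), "statistic": np.nan,
                 "p_value": np.nan, "status": "insufficient"}
            )
            continue
        res = logrank_test(sub["time"], sub["event"], sub["label"])
        rows.append(
            {"stratum": value, "n": len(sub), "statistic": res.statistic,
             "p_value": res.p_value, "status": "ok"}
        )
    return pd.DataFrame(rows).set_index("stratum")
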