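"""Survival endpoints: Kaplan–Meier, log-rank, reverse-KM follow-up.

Times are months from the day of surgery. ``event`` is death for overall
survival or recurrence-or-death for disease-free survival. Estimation is
the product-limit (Kaplan–Meier) estimator with the standard convention
that events precede censorings tied at the same time; group comparison is
the Mantel–Cox log-rank test; median follow-up uses the reverse
Kaplan–Meier method (censoring treated as the event) with a Greenwood
log–log 95% confidence interval. The fitting itself is delegated to
lifelines behind this module's interface.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from lifelines.utils import median_survival_times

from .errors import DataError, UndefinedStatisticError

__all__ = [
    "SurvivalRecord",
    "KMEstimate",
    "km_estimate",
    "logrank_test",
    "reverse_km_followup",
    "read_survival_csv",
]


@dataclass(frozen=True)
class SurvivalRecord:
    patient_id: str
    time: float  # months since surgery
    event: bool
    group: str | None = None

    def __post_init__(self) -> None:
        if self.time < 0:
            raise DataError(f"patient {self.patient_id!r}: negative time {self.time}")


@dataclass(frozen=True)
class KMEstimate:
    """A fitted survival curve with its at-risk bookkeeping."""

    times: np.ndarray        # distinct event/censor times, ascending
    survival: np.ndarray     # S(t) right after each time (right-continuous)
    at_risk: np.ndarray      # number at risk just before each time
    removed: np.ndarray      # events + censorings occurring at each time
    n: int

    def survival_at(self, t: float) -> float:
        """S(t) of the right-continuous step function."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def at_risk_at(self, t: float) -> int:
        """Number at risk just before time t (for at-risk tables)."""
        before = self.times < t
        return int(self.n - self.removed[before].sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "survival": self.survival,
                "at_risk": self.at_risk,
                "removed": self.removed,
            }
        )


def _to_arrays(records: Sequence[SurvivalRecord]) -> tuple[np.ndarray, np.ndarray]:
    if not records:
        raise DataError("no survival records")
    times = np.array([r.time for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=bool)
    return times, events


def km_estimate(records: Sequence[SurvivalRecord]) -> KMEstimate:
    """Product-limit estimate S(t) = Π_{t_i ≤ t} (1 − d_i/n_i).

    Returns the curve evaluated at every distinct observed time together
    with the at-risk count just before that time.
    """
    times, events = _to_arrays(records)
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    # event_table is indexed by distinct times (lifelines pads a t=0 row
    # when no subject has time 0; keep only observed times)
    table = kmf.event_table[kmf.event_table.index.isin(np.unique(times))]
    grid = table.index.to_numpy(dtype=float)
    surv = np.array([float(kmf.predict(t)) for t in grid])
    return KMEstimate(
        times=grid,
        survival=surv,
        at_risk=table["at_risk"].to_numpy(dtype=int),
        removed=table["removed"].to_numpy(dtype=int),
        n=len(records),
    )


def logrank_test(
    a: Sequence[SurvivalRecord], b: Sequence[SurvivalRecord]
) -> tuple[float, float]:
    """Mantel–Cox log-rank comparison of two groups.

    Returns (chi-square statistic on 1 df, two-sided p). Undefined when
    the pooled data contain no events.
    """
    ta, ea = _to_arrays(a)
    tb, eb = _to_arrays(b)
    if not (ea.any() or eb.any()):
        raise UndefinedStatisticError("logrank_test: no events in pooled data")
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)


def reverse_km_followup(
    records: Sequence[SurvivalRecord], alpha: float = 0.05
) -> tuple[float, tuple[float, float]]:
    """Median follow-up by the reverse Kaplan–Meier method.

    Applies the product-limit estimator with the event indicator flipped
    (censored patients are the "events"; deaths are censored), and reads
    off the median with its Greenwood log–log confidence interval.
    Raises :class:`UndefinedStatisticError` when the flipped curve never
    reaches 0.5.
    """
    times, events = _to_arrays(records)
    kmf = KaplanMeierFitter(alpha=alpha)
    kmf.fit(times, event_observed=~events)
    median = float(kmf.median_survival_time_)
    if not np.isfinite(median):
        raise UndefinedStatisticError(
            "reverse_km_followup: follow-up curve never reaches 0.5"
        )
    ci = median_survival_times(kmf.confidence_interval_)
    lo, hi = float(ci.iloc[0, 0]), float(ci.iloc[0, 1])
    return median, (lo, hi)


def read_survival_csv(path) -> list[SurvivalRecord]:
    """Read a survival table: patient_id, time, event[, group]."""
    df = pd.read_csv(path)
    required = {"patient_id", "time", "event"}
    if not required <= set(df.columns):
        raise DataError(f"{path}: need columns {sorted(required)}")
    return [
        SurvivalRecord(
            patient_id=str(r["patient_id"]),
            time=float(r["time"]),
            event=bool(int(r["event"])),
            group=str(r["group"]) if "group" in df.columns and pd.notna(r["group"]) else None,
        )
        for _, r in df.iterrows()
    ]
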