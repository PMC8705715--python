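"""Per-participant baseline calibration and the 7-day rolling monitor.

A 14-day baseline of morning readings establishes each individual's mean and
sample SD of the daily HRV score, from which the SWC1 (±0.5 SD) and SWC2
(±1 SD) windows are derived. During training, decisions are driven not by
single-day values but by the trailing 7-calendar-day rolling average, which is
less noisy and tracks sustained shifts. Midway through a program the baseline
is recalculated from recent readings, because training itself shifts resting
HRV.

Missing days: the rolling average is the mean of the readings available in the
window, requiring a configurable minimum (default 4 of 7); the baseline
requires a minimum count (default 10 of 14).
"""

from __future__ import annotations

import dataclasses
import datetime
from collections.abc import Iterable, Sequence

from .hrv import DailyReading
from .prescriber import SWCPrescriber

__all__ = [
    "BaselineProfile",
    "RollingState",
    "ProfileHistory",
    "calibrate_baseline",
    "recalibrate",
    "rolling_hrv7",
]


@dataclasses.dataclass(frozen=True)
class BaselineProfile:
    """Calibrated baseline statistics and SWC window bounds for one person."""

    participant_id: str
    mean: float
    sd: float
    swc1_lo: float
    swc1_hi: float
    swc2_lo: float
    swc2_hi: float
    n_days: int
    period: tuple[datetime.date, datetime.date]
    degenerate: bool = False
    carried_forward: bool = False

    def __post_init__(self) -> None:
        if not (self.swc2_lo <= self.swc1_lo <= self.swc1_hi <= self.swc2_hi):
            raise ValueError("SWC windows must be nested: swc2 contains swc1")


@dataclasses.dataclass(frozen=True)
class RollingState:
    """Trailing 7-day rolling average of the daily score on a given date.

    ``hrv7`` is None (with ``reason``) when fewer than the minimum number of
    readings fall inside the window.
    """

    participant_id: str
    date: datetime.date
    hrv7: float | None
    n_in_window: int
    reason: str | None = None


class ProfileHistory:
    """Audit trail of successive baseline profiles for one participant."""

    def __init__(self) -> None:
        self._profiles: list[BaselineProfile] = []

    def update(self, profile: BaselineProfile) -> BaselineProfile:
        self._profiles.append(profile)
        return profile

    @property
    def current(self) -> BaselineProfile:
        if not self._profiles:
            raise ValueError("no profile has been calibrated yet")
        return self._profiles[-1]

    @property
    def history(self) -> tuple[BaselineProfile, ...]:
        return tuple(self._profiles)


def _dedupe(readings: Iterable[DailyReading]) -> list[DailyReading]:
    seen: dict[datetime.date, DailyReading] = {}
    for r in readings:
        if r.date in seen:
            raise ValueError(f"duplicate reading for {r.participant_id} on {r.date}")
        seen[r.date] = r
    return [seen[d] for d in sorted(seen)]


def calibrate_baseline(readings: Sequence[DailyReading], window_days: int = 14,
                       min_days: int = 10, swc1: float = 0.5, swc2: float = 1.0,
                       ddof: int = 1) -> BaselineProfile:
    """Baseline mean/SD of the daily score and the SWC windows around it.

    ``readings`` must all fall within a span of ``window_days`` calendar days
    and contain at least ``min_days`` distinct days. A zero-SD input yields a
    degenerate profile (both windows collapse onto the mean) flagged as such.
    """
    readings = _dedupe(readings)
    if len(readings) < min_days:
        raise ValueError(
            f"insufficient baseline: {len(readings)} readings, need >= {min_days}"
        )
    span = (readings[-1].date - readings[0].date).days + 1
    if span > window_days:
        raise ValueError(
            f"baseline readings span {span} days, exceeding the {window_days}-day window"
        )
    est = SWCPrescriber(swc1=swc1, swc2=swc2, min_days=min_days, ddof=ddof)
    est.fit([r.hrv_daily for r in readings])
    return BaselineProfile(
        participant_id=readings[0].participant_id,
        mean=est.mean_,
        sd=est.sd_,
        swc1_lo=est.swc1_bounds_[0],
        swc1_hi=est.swc1_bounds_[1],
        swc2_lo=est.swc2_bounds_[0],
        swc2_hi=est.swc2_bounds_[1],
        n_days=est.n_days_,
        period=(readings[0].date, readings[-1].date),
        degenerate=est.degenerate_,
    )


def recalibrate(readings: Sequence[DailyReading], as_of: datetime.date,
                window_days: int = 14, min_days: int = 10,
                prior: BaselineProfile | None = None, carry_forward: bool = False,
                swc1: float = 0.5, swc2: float = 1.0,
                ddof: int = 1) -> BaselineProfile:
    """Recalculate the baseline from the most recent readings before ``as_of``.

    Uses readings with ``as_of - window_days <= date < as_of``. If too few are
    available and ``carry_forward`` is true, the ``prior`` profile is returned
    flagged ``carried_forward``; otherwise an error is raised.
    """
    lo = as_of - datetime.timedelta(days=window_days)
    window = [r for r in readings if lo <= r.date < as_of]
    try:
        return calibrate_baseline(window, window_days=window_days, min_days=min_days,
                                  swc1=swc1, swc2=swc2, ddof=ddof)
    except ValueError:
        if carry_forward and prior is not None:
            return dataclasses.replace(prior, carried_forward=True)
        raise


def rolling_hrv7(readings: Sequence[DailyReading], date: datetime.date,
                 window_days: int = 7, min_readings: int = 4) -> RollingState:
    """Trailing rolling average of the daily score over (date-6 ... date).

    Returns a defined state (mean of available readings) when at least
    ``min_readings`` fall inside the window, else an undefined state carrying
    the reason.
    """
    lo = date - datetime.timedelta(days=window_days - 1)
    window = _dedupe(r for r in readings if lo <= r.date <= date)
    pid = readings[0].participant_id if readings else ""
    if len(window) < min_readings:
        return RollingState(pid, date, None, len(window),
                            reason=f"insufficient readings: {len(window)} < {min_readings}")
    mean = sum(r.hrv_daily for r in window) / len(window)
    return RollingState(window[0].participant_id, date, mean, len(window))
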