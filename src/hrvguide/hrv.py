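"""Daily heart-rate-variability scores from raw R-R interval recordings.

Day-to-day athlete monitoring uses the vagally mediated time-domain index
RMSSD (root mean square of successive differences between adjacent inter-beat
intervals, in ms). Because RMSSD is right-skewed across people, it is
log-transformed, and here additionally multiplied by two so the resulting
score sits on a convenient ~1-10 display scale:

    hrv_daily = 2 * ln(RMSSD)

A reading taken each morning (supine, on waking) yields one ``DailyReading``
per participant per calendar day; the day-to-day coefficient of variation of
the score over a trailing window indexes how noisy an individual's autonomic
state is.

Raw inter-beat series from consumer photoplethysmography contain artifacts
(missed/extra beats, ectopy). ``filter_rr`` removes intervals that deviate
strongly from their local median before RMSSD is computed.
"""

from __future__ import annotations

import dataclasses
import datetime
import math
from collections.abc import Sequence

import numpy as np

__all__ = [
    "RRSeries",
    "DailyReading",
    "filter_rr",
    "rmssd",
    "hrv_daily_score",
    "cv_of_hrv",
]


@dataclasses.dataclass(frozen=True)
class RRSeries:
    """An ordered morning recording of inter-beat (R-R) intervals in ms."""

    participant_id: str
    date: datetime.date
    intervals: tuple[float, ...]

    def __post_init__(self) -> None:
        intervals = tuple(float(x) for x in self.intervals)
        if any(not math.isfinite(x) or x <= 0 for x in intervals):
            raise ValueError("all R-R intervals must be finite and strictly positive (ms)")
        object.__setattr__(self, "intervals", intervals)

    def __len__(self) -> int:
        return len(self.intervals)


@dataclasses.dataclass(frozen=True)
class DailyReading:
    """One morning measurement: RMSSD (ms), its 2*ln score, optional resting HR.

    ``hrv_daily`` is derived from ``rmssd_ms`` when not supplied; when both are
    supplied they must be consistent to numerical tolerance.
    """

    participant_id: str
    date: datetime.date
    rmssd_ms: float
    hrv_daily: float | None = None
    rhr_bpm: float | None = None

    def __post_init__(self) -> None:
        if self.rmssd_ms is None or not math.isfinite(self.rmssd_ms) or self.rmssd_ms <= 0:
            raise ValueError(f"rmssd_ms must be a positive finite number, got {self.rmssd_ms!r}")
        score = hrv_daily_score(self.rmssd_ms)
        if self.hrv_daily is None:
            object.__setattr__(self, "hrv_daily", score)
        elif not math.isclose(self.hrv_daily, score, rel_tol=1e-6, abs_tol=1e-6):
            raise ValueError(
                f"hrv_daily={self.hrv_daily} inconsistent with 2*ln(rmssd_ms)={score:.6f}"
            )
        if self.rhr_bpm is not None and self.rhr_bpm <= 0:
            raise ValueError("rhr_bpm must be positive when present")


def _filter_pass(values: list[float], rel_threshold: float) -> list[float]:
    """One sweep: drop intervals deviating > rel_threshold from the median of
    the 5-interval window centred on them (window truncated at the edges)."""
    arr = np.asarray(values, dtype=float)
    kept: list[float] = []
    for i, v in enumerate(values):
        window = arr[max(0, i - 2) : i + 3]
        med = float(np.median(window))
        if abs(v - med) / med <= rel_threshold:
            kept.append(v)
    return kept


def filter_rr(series: RRSeries, rel_threshold: float = 0.3) -> tuple[RRSeries, int]:
    """Remove artifactual intervals; returns (filtered series, count removed).

    An interval is artifactual when its relative deviation from the median of
    its 5-interval neighbourhood exceeds ``rel_threshold``. The sweep is
    iterated to a fixed point so that the filter is idempotent even when
    adjacent artifacts mask one another on the first pass. Order is preserved.
    """
    if not 0 < rel_threshold < 1:
        raise ValueError("rel_threshold must lie in (0, 1)")
    if len(series) == 0:
        raise ValueError("no intervals")
    values = list(series.intervals)
    removed = 0
    while values:
        kept = _filter_pass(values, rel_threshold)
        if len(kept) == len(values):
            break
        removed += len(values) - len(kept)
        values = kept
    return dataclasses.replace(series, intervals=tuple(values)), removed


def rmssd(series: RRSeries | Sequence[float]) -> float:
    """Root mean square of successive differences of R-R intervals, in ms."""
    intervals = series.intervals if isinstance(series, RRSeries) else tuple(series)
    if len(intervals) < 2:
        raise ValueError("at least 2 intervals are required to compute RMSSD")
    diffs = np.diff(np.asarray(intervals, dtype=float))
    return float(np.sqrt(np.mean(diffs**2)))


def hrv_daily_score(rmssd_ms: float) -> float:
    """Dimensionless daily HRV score, 2*ln(RMSSD in ms)."""
    if not math.isfinite(rmssd_ms) or rmssd_ms <= 0:
        raise ValueError(f"rmssd_ms must be positive, got {rmssd_ms!r}")
    return 2.0 * math.log(rmssd_ms)


def cv_of_hrv(scores: Sequence[float], window_days: int = 7) -> float:
    """Coefficient of variation (%) of daily scores over the trailing window.

    ``scores`` are consecutive daily values, most recent last; the trailing
    ``window_days`` of them are used (sample SD, n-1 denominator).
    """
    if window_days < 2:
        raise ValueError("window_days must be >= 2")
    windowed = np.asarray(scores[-window_days:], dtype=float)
    if windowed.size < 2:
        raise ValueError("at least 2 scores are required inside the window")
    mean = float(np.mean(windowed))
    if mean <= 0:
        raise ValueError("mean of windowed scores must be positive for a CV")
    sd = float(np.std(windowed, ddof=1))
    return 100.0 * sd / mean
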