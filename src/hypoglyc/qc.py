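"""Day-level quality control: warm-up trimming, calendar-day segmentation,
completeness, eligibility and the nocturnal window.

A biomarker day is the local calendar day, the half-open interval
[00:00, 24:00). With one sample every 15 minutes a complete day holds 96
samples; a day is *valid* when at least 80% of those expected samples were
recorded, and a subject is *eligible* when at least two days are valid.
The first hours after sensor insertion are unreliable (warm-up) and are
trimmed before segmentation.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace

import numpy as np

from .io import SensorTrace


class ConfigurationError(ValueError):
    """Raised for inconsistent QC or window configuration."""


def _parse_clock(value) -> dt.time:
    if isinstance(value, dt.time):
        return value
    if isinstance(value, str):
        hh, mm = value.split(":")
        return dt.time(int(hh), int(mm))
    raise ConfigurationError(f"cannot interpret clock time {value!r}")


@dataclass
class QCConfig:
    """Quality-control parameters for day building.

    expected_per_day : int
        Samples a complete day would hold (96 at 15-min sampling).
    min_completeness : float
        Fraction of expected samples a day needs to be valid (0.80).
    min_valid_days : int
        Valid days a subject needs to enter the analysis (2).
    warmup_hours : float
        Hours discarded from the start of each recording (sensor warm-up).
    night_start, night_end : datetime.time
        Clock bounds of the nocturnal window, half-open [start, end).
    """

    expected_per_day: int = 96
    min_completeness: float = 0.80
    min_valid_days: int = 2
    warmup_hours: float = 3.0
    night_start: dt.time = dt.time(0, 0)
    night_end: dt.time = dt.time(6, 0)

    def __post_init__(self) -> None:
        self.night_start = _parse_clock(self.night_start)
        self.night_end = _parse_clock(self.night_end)
        if not 0 < self.min_completeness <= 1:
            raise ConfigurationError("min_completeness must be in (0, 1]")
        if self.expected_per_day <= 0 or 1440 % self.expected_per_day:
            raise ConfigurationError(
                "expected_per_day must divide the 1440 minutes of a day"
            )
        if self.warmup_hours < 0:
            raise ConfigurationError("warmup_hours must be non-negative")
        if self.min_valid_days < 1:
            raise ConfigurationError("min_valid_days must be at least 1")

    @property
    def nominal_interval(self) -> float:
        """Nominal sampling interval in minutes implied by expected_per_day."""
        return 1440.0 / self.expected_per_day


@dataclass
class DayWindow:
    """Samples of one calendar day with its completeness and validity flag."""

    subject_id: str
    date: dt.date
    times: np.ndarray
    glucose: np.ndarray
    completeness: float
    valid: bool
    expected_samples: int

    @property
    def n_samples(self) -> int:
        return int(self.times.size)


def trim_warmup(trace: SensorTrace, qc: QCConfig) -> SensorTrace:
    """Drop samples within ``warmup_hours`` of the first recorded sample."""
    if trace.n_samples == 0 or qc.warmup_hours == 0:
        return trace
    cutoff = trace.times[0] + np.timedelta64(
        int(round(qc.warmup_hours * 3600)), "s"
    )
    keep = trace.times >= cutoff
    return SensorTrace(
        trace.subject_id, trace.times[keep], trace.glucose[keep],
        trace.nominal_interval,
    )


def segment_days(trace: SensorTrace, qc: QCConfig) -> list[DayWindow]:
    """Split a (trimmed) trace into calendar-day windows.

    Each sample belongs to exactly one window by its date; only dates with at
    least one sample produce a window. Completeness is the duplicate-free
    sample count over ``expected_per_day``.
    """
    if trace.n_samples == 0:
        return []
    days = trace.times.astype("datetime64[D]")
    windows: list[DayWindow] = []
    # times are sorted, so each day's samples are one contiguous slice
    boundaries = np.flatnonzero(np.diff(days).astype(int)) + 1
    for chunk in np.split(np.arange(trace.n_samples), boundaries):
        idx = chunk
        completeness = idx.size / qc.expected_per_day
        windows.append(
            DayWindow(
                subject_id=trace.subject_id,
                date=days[idx[0]].item(),
                times=trace.times[idx],
                glucose=trace.glucose[idx],
                completeness=completeness,
                valid=completeness >= qc.min_completeness,
                expected_samples=qc.expected_per_day,
            )
        )
    return windows


def eligible_days(windows: list[DayWindow], qc: QCConfig) -> tuple[list[DayWindow], bool]:
    """Keep valid windows and flag whether the subject is eligible.

    Eligibility requires at least ``min_valid_days`` valid days.
    """
    valid = [w for w in windows if w.valid]
    return valid, len(valid) >= qc.min_valid_days


def _minutes_of_day(times: np.ndarray) -> np.ndarray:
    return (
        (times - times.astype("datetime64[D]")).astype("timedelta64[s]").astype(float)
        / 60.0
    )


def night_window(window: DayWindow, qc: QCConfig) -> DayWindow:
    """Restrict a day window to the nocturnal clock interval.

    The interval is half-open [night_start, night_end) on the local clock; an
    interval wrapping midnight (e.g. 22:00–06:00) selects both clock ranges
    within the same calendar day. Completeness is re-based on the number of
    nominal-grid samples the interval can hold, and validity re-evaluated
    against the same ``min_completeness`` threshold.
    """
    start = qc.night_start.hour * 60 + qc.night_start.minute
    end = qc.night_end.hour * 60 + qc.night_end.minute
    if start == end:
        raise ConfigurationError("night window must have non-zero length")
    minutes = _minutes_of_day(window.times)
    if start < end:
        mask = (minutes >= start) & (minutes < end)
        span = end - start
    else:  # wraps midnight: [start, 24:00) ∪ [00:00, end)
        mask = (minutes >= start) | (minutes < end)
        span = (1440 - start) + end
    expected = int(round(span / qc.nominal_interval))
    n = int(mask.sum())
    completeness = n / expected if expected else 0.0
    return DayWindow(
        subject_id=window.subject_id,
        date=window.date,
        times=window.times[mask],
        glucose=window.glucose[mask],
        completeness=completeness,
        valid=completeness >= qc.min_completeness,
        expected_samples=expected,
    )
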