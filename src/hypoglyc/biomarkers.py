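"""Hypoglycaemic episode detection and the four daily glycaemic biomarkers.

An episode is a maximal run of samples strictly below the hypoglycaemia
threshold (70 mg/dL) containing at least two measurements, in which every
adjacent pair of measurements is no more than 30 minutes apart. A single
isolated sub-threshold sample is not an episode, and a data gap longer than
the pairing window splits a run in two.

The episode's severity is its threshold-deficit area under the curve: the
trapezoidal integral of (threshold − glucose) over the episode's samples
against real elapsed time, in mg/dL·min. Only sub-threshold samples enter the
integral; the crossing of the threshold between a normal and a low sample is
not interpolated.

Per valid day the four biomarkers are: mean glycaemia, minimum glycaemia,
coefficient of variation (sample SD over mean) and total hypoglycaemic AUC
(sum over the day's episodes, 0 for a day without episodes). The subject-level
biomarker is the unweighted mean of the daily values across valid days.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np

from .qc import DayWindow


class IneligibleSubjectError(ValueError):
    """Raised when a subject has fewer valid days than required."""


@dataclass
class DetectorConfig:
    """Episode-detector constants.

    threshold : float
        Hypoglycaemia bound in mg/dL; samples strictly below count (70).
    min_consecutive : int
        Minimum number of consecutive sub-threshold measurements (2).
    max_pair_gap : float
        Maximum minutes between adjacent measurements of an episode (30).
    """

    threshold: float = 70.0
    min_consecutive: int = 2
    max_pair_gap: float = 30.0

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be positive mg/dL")
        if self.min_consecutive < 2:
            raise ValueError("an episode needs at least two measurements")
        if self.max_pair_gap <= 0:
            raise ValueError("max_pair_gap must be positive minutes")


@dataclass
class HypoEpisode:
    """A detected hypoglycaemic episode with its threshold-deficit AUC."""

    times: np.ndarray
    glucose: np.ndarray
    start: np.datetime64
    end: np.datetime64
    auc: float

    @property
    def n_samples(self) -> int:
        return int(self.times.size)


@dataclass
class DailyBiomarkers:
    date: dt.date
    n_samples: int
    mean_glycaemia: float
    min_glycaemia: float
    cv: float
    hypo_auc: float
    n_episodes: int


@dataclass
class SubjectBiomarkers:
    """Per-subject biomarkers: means of the daily values across valid days."""

    subject_id: str
    n_valid_days: int
    mean_glycaemia: float
    min_glycaemia: float
    cv: float
    hypo_auc: float
    n_episodes: float


def _minutes_between(times: np.ndarray) -> np.ndarray:
    return np.diff(times).astype("timedelta64[s]").astype(float) / 60.0


def episode_auc(episode: HypoEpisode | None = None, det: DetectorConfig | None = None,
                *, times: np.ndarray | None = None,
                glucose: np.ndarray | None = None) -> float:
    """Trapezoidal threshold-deficit AUC of an episode, in mg/dL·min.

    The deficit ``threshold − glucose`` is integrated against real time
    deltas in minutes over the episode's (sub-threshold) samples.
    """
    det = det or DetectorConfig()
    if episode is not None:
        times, glucose = episode.times, episode.glucose
    deficit = det.threshold - np.asarray(glucose, dtype=float)
    if np.any(deficit <= 0):
        raise ValueError("episode samples must all be below threshold")
    dt_min = _minutes_between(np.asarray(times, dtype="datetime64[s]"))
    return float(np.sum((deficit[:-1] + deficit[1:]) / 2.0 * dt_min))


def detect_episodes(times: np.ndarray, glucose: np.ndarray,
                    det: DetectorConfig | None = None) -> list[HypoEpisode]:
    """Find all hypoglycaemic episodes in a time-ordered sample sequence.

    Returns maximal runs of strictly-sub-threshold samples whose adjacent
    timestamps are at most ``max_pair_gap`` minutes apart; runs shorter than
    ``min_consecutive`` are discarded. Episodes are disjoint and returned in
    time order, each with its AUC filled in.
    """
    det = det or DetectorConfig()
    times = np.asarray(times, dtype="datetime64[s]")
    glucose = np.asarray(glucose, dtype=float)
    below = glucose < det.threshold
    episodes: list[HypoEpisode] = []
    i = 0
    n = times.size
    while i < n:
        if not below[i]:
            i += 1
            continue
        j = i + 1
        while j < n and below[j]:
            gap = (times[j] - times[j - 1]).astype("timedelta64[s]").astype(float) / 60.0
            if gap > det.max_pair_gap:
                break
            j += 1
        if j - i >= det.min_consecutive:
            ep_times = times[i:j]
            ep_glucose = glucose[i:j]
            episodes.append(
                HypoEpisode(
                    times=ep_times,
                    glucose=ep_glucose,
                    start=ep_times[0],
                    end=ep_times[-1],
                    auc=episode_auc(det=det, times=ep_times, glucose=ep_glucose),
                )
            )
        i = j
    return episodes


def daily_biomarkers(window: DayWindow, det: DetectorConfig | None = None) -> DailyBiomarkers:
    """Compute the four biomarkers for one valid day window.

    mean/min are over all of the day's samples (a single isolated sub-70
    sample lowers the minimum even though it forms no episode); CV uses the
    n−1 sample standard deviation; hypo AUC sums over detected episodes and
    is 0 for a day with none.
    """
    det = det or DetectorConfig()
    if not window.valid:
        raise ValueError(
            f"day {window.date} of subject {window.subject_id!r} failed "
            "completeness QC; biomarkers are only defined for valid days"
        )
    g = window.glucose
    mean = float(g.mean())
    episodes = detect_episodes(window.times, g, det)
    return DailyBiomarkers(
        date=window.date,
        n_samples=window.n_samples,
        mean_glycaemia=mean,
        min_glycaemia=float(g.min()),
        cv=float(g.std(ddof=1) / mean) if g.size > 1 else 0.0,
        hypo_auc=float(sum(ep.auc for ep in episodes)),
        n_episodes=len(episodes),
    )


def aggregate_subject(dailies: list[DailyBiomarkers], subject_id: str,
                      min_valid_days: int = 2) -> SubjectBiomarkers:
    """Average the daily biomarkers into the subject-level biomarkers.

    Subjects with fewer than ``min_valid_days`` valid days are ineligible.
    The aggregate is the unweighted arithmetic mean across days, so it is
    invariant to day order.
    """
    if len(dailies) < min_valid_days:
        raise IneligibleSubjectError(
            f"subject {subject_id!r} has {len(dailies)} valid day(s); "
            f"{min_valid_days} required"
        )
    mean_of = lambda attr: float(np.mean([getattr(d, attr) for d in dailies]))
    return SubjectBiomarkers(
        subject_id=subject_id,
        n_valid_days=len(dailies),
        mean_glycaemia=mean_of("mean_glycaemia"),
        min_glycaemia=mean_of("min_glycaemia"),
        cv=mean_of("cv"),
        hypo_auc=mean_of("hypo_auc"),
        n_episodes=mean_of("n_episodes"),
    )
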