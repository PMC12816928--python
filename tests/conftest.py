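import datetime as dt

import numpy as np
import pytest

from hypoglyc import DetectorConfig, QCConfig, SensorTrace


def make_trace(minutes, glucose, subject_id="T001", start="2024-01-01T00:00:00"):
    """Build a trace from minute offsets relative to ``start``."""
    t0 = np.datetime64(start, "s")
    times = t0 + (np.asarray(minutes, dtype=np.int64) * 60).astype("timedelta64[s]")
    return SensorTrace(subject_id, times, np.asarray(glucose, dtype=float))


def grid_day(n_samples=96, value=90.0, date="2024-01-02", interval=15):
    """A single calendar day on the nominal grid with constant glucose."""
    minutes = np.arange(n_samples) * interval
    return make_trace(minutes, np.full(n_samples, value), start=f"{date}T00:00:00")


def brute_force_episodes(times, glucose, det):
    """Independent episode oracle: enumerate every contiguous index range,
    keep those whose samples are all sub-threshold with every adjacent pair
    within the gap limit, then retain the maximal ones of sufficient length.
    Returns (start_index, end_index_inclusive) pairs."""
    times = np.asarray(times, dtype="datetime64[s]")
    glucose = np.asarray(glucose, dtype=float)
    n = len(times)
    candidates = []
    for i in range(n):
        for j in range(i, n):
            if not np.all(glucose[i:j + 1] < det.threshold):
                continue
            gaps = np.diff(times[i:j + 1]).astype("timedelta64[s]").astype(float) / 60.0
            if np.all(gaps <= det.max_pair_gap):
                candidates.append((i, j))
    maximal = [
        (i, j)
        for (i, j) in candidates
        if not any(a <= i and j <= b and (a, b) != (i, j) for (a, b) in candidates)
    ]
    return [(i, j) for (i, j) in maximal if j - i + 1 >= det.min_consecutive]


def random_short_trace(rng, max_len=30, lo=50.0, hi=110.0):
    """A short random trace with random gaps, for oracle comparisons."""
    n = int(rng.integers(0, max_len + 1))
    gaps = rng.choice([15, 15, 15, 30, 45, 60], size=max(n - 1, 0))
    minutes = np.concatenate([[0], np.cumsum(gaps)]) if n else np.array([], dtype=int)
    glucose = rng.uniform(lo, hi, size=n)
    return make_trace(minutes[:n], glucose)


@pytest.fixture
def qc():
    return QCConfig()


@pytest.fixture
def det():
    return DetectorConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(20240101)
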