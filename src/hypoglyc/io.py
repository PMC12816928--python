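"""Reading and writing CGM traces and subject covariate tables.

The canonical trace format is a plain CSV with header
``subject_id,timestamp,glucose_mg_dl`` (or ``glucose_mmol_l``, converted on
read), ISO-8601 naive local timestamps at minute resolution, and glucose
written with two decimals. Covariate tables are CSV with header
``subject_id,age,bmi,illness_duration,edi2_total``; empty cells are preserved
as missing values so that the statistical stage can apply pairwise or
complete-case deletion itself.

Timestamps are deliberately timezone-naive: the day-level analysis is defined
on the local clock (midnight to midnight), so wall-clock time is the relevant
axis.
"""

from __future__ import annotations

import csv
import gzip
import math
from dataclasses import dataclass, field
from typing import IO, Iterator

import numpy as np
import pandas as pd

#: Conversion factor from mmol/L to mg/dL for glucose.
MMOL_TO_MGDL = 18.016

TRACE_HEADER = ["subject_id", "timestamp", "glucose_mg_dl"]
TRACE_HEADER_MMOL = ["subject_id", "timestamp", "glucose_mmol_l"]
COVARIATE_HEADER = ["subject_id", "age", "bmi", "illness_duration", "edi2_total"]


class TraceFormatError(ValueError):
    """Raised when a trace file violates the canonical format."""


class CovariateFormatError(ValueError):
    """Raised when a covariate file violates the canonical format."""


@dataclass(frozen=True)
class SubjectRecord:
    """One subject's covariates.

    Missing values are represented as ``nan``; the reader never drops a row
    for missingness — downstream stages decide how to handle it.
    """

    subject_id: str
    age: float
    bmi: float
    illness_duration: float
    edi2_total: float

    def has(self, name: str) -> bool:
        value = getattr(self, name)
        return not (isinstance(value, float) and math.isnan(value))


@dataclass
class SensorTrace:
    """A single subject's interstitial-glucose time series.

    Parameters
    ----------
    subject_id
        Opaque identifier.
    times
        ``datetime64[s]`` array of sample timestamps, strictly increasing.
    glucose
        Glucose in mg/dL, strictly positive, same length as ``times``.
    nominal_interval
        Nominal sampling interval of the sensor in minutes (15 for the
        devices modelled here). Gaps are allowed; the interval is nominal.
    """

    subject_id: str
    times: np.ndarray
    glucose: np.ndarray
    nominal_interval: int = 15

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype="datetime64[s]")
        self.glucose = np.asarray(self.glucose, dtype=float)
        if self.times.shape != self.glucose.shape or self.times.ndim != 1:
            raise ValueError("times and glucose must be 1-D arrays of equal length")
        if self.times.size:
            deltas = np.diff(self.times)
            if np.any(deltas <= np.timedelta64(0, "s")):
                raise TraceFormatError(
                    f"timestamps for subject {self.subject_id!r} must be "
                    "strictly increasing with no duplicates"
                )
            if np.any(self.glucose <= 0):
                raise TraceFormatError(
                    f"non-positive glucose value in trace for {self.subject_id!r}"
                )
        if self.nominal_interval <= 0:
            raise ValueError("nominal_interval must be positive minutes")

    @property
    def n_samples(self) -> int:
        return int(self.times.size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": self.subject_id,
                "timestamp": self.times,
                "glucose_mg_dl": self.glucose,
            }
        )


def _open_text(path, mode: str) -> IO[str]:
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode + "t", newline="")
    return open(path, mode, newline="")


def _parse_trace_rows(path) -> Iterator[tuple[int, str, np.datetime64, float]]:
    """Yield (line_number, subject_id, timestamp, glucose_mg_dl) rows."""
    with _open_text(path, "r") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise TraceFormatError(f"{path}: empty file, expected a header row")
        if header == TRACE_HEADER:
            factor = 1.0
        elif header == TRACE_HEADER_MMOL:
            factor = MMOL_TO_MGDL
        else:
            raise TraceFormatError(
                f"{path}: unrecognized header {header!r}; expected "
                f"{TRACE_HEADER!r} or {TRACE_HEADER_MMOL!r}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 3:
                raise TraceFormatError(f"{path}, line {lineno}: expected 3 fields")
            sid, ts_str, g_str = row
            try:
                ts = np.datetime64(ts_str, "s")
                glucose = float(g_str) * factor
            except (ValueError, TypeError):
                raise TraceFormatError(
                    f"{path}, line {lineno}: unparseable row {row!r}"
                ) from None
            if glucose <= 0:
                raise TraceFormatError(
                    f"{path}, line {lineno}: non-positive glucose {g_str}"
                )
            yield lineno, sid, ts, glucose


def read_traces(path, dialect: str = "canonical") -> list[SensorTrace]:
    """Read a canonical trace CSV possibly holding several subjects.

    Rows must be grouped by subject and time-ordered within each subject;
    duplicate timestamps within a subject are rejected. A ``glucose_mmol_l``
    header triggers conversion to mg/dL by the factor 18.016.
    """
    if dialect != "canonical":
        raise ValueError(f"unknown trace dialect {dialect!r}")
    traces: list[SensorTrace] = []
    seen: set[str] = set()
    cur_id: str | None = None
    cur_times: list[np.datetime64] = []
    cur_glucose: list[float] = []

    def flush() -> None:
        if cur_id is not None:
            traces.append(
                SensorTrace(cur_id, np.array(cur_times, dtype="datetime64[s]"),
                            np.array(cur_glucose))
            )

    for lineno, sid, ts, glucose in _parse_trace_rows(path):
        if sid != cur_id:
            if sid in seen:
                raise TraceFormatError(
                    f"{path}, line {lineno}: rows for subject {sid!r} are not "
                    "contiguous"
                )
            flush()
            cur_id = sid
            seen.add(sid)
            cur_times, cur_glucose = [], []
        if cur_times and ts <= cur_times[-1]:
            raise TraceFormatError(
                f"{path}, line {lineno}: duplicate or out-of-order timestamp "
                f"{ts} for subject {sid!r}"
            )
        cur_times.append(ts)
        cur_glucose.append(glucose)
    flush()
    return traces


def read_trace(path, dialect: str = "canonical") -> SensorTrace:
    """Read a canonical trace CSV containing exactly one subject.

    An empty file with a valid header yields a trace with zero samples and an
    empty subject id.
    """
    traces = read_traces(path, dialect=dialect)
    if len(traces) > 1:
        raise TraceFormatError(
            f"{path}: expected a single subject, found {len(traces)}"
        )
    if not traces:
        return SensorTrace("", np.array([], dtype="datetime64[s]"), np.array([]))
    return traces[0]


def _format_ts(ts: np.datetime64) -> str:
    return np.datetime_as_string(ts.astype("datetime64[s]"))


def write_traces(traces: list[SensorTrace], path) -> None:
    """Write traces to the canonical CSV (glucose with two decimals)."""
    with _open_text(path, "w") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(TRACE_HEADER)
        for trace in traces:
            for ts, g in zip(trace.times, trace.glucose):
                writer.writerow([trace.subject_id, _format_ts(ts), f"{g:.2f}"])


def write_trace(trace: SensorTrace, path) -> None:
    """Write a single trace to the canonical CSV."""
    write_traces([trace], path)


def read_covariates(path) -> list[SubjectRecord]:
    """Read the subject covariate table.

    Empty cells become ``nan`` and the record is kept: the reader does not
    enforce study eligibility (for example the underweight BMI bound), which
    is the analysis stage's decision.
    """
    with _open_text(path, "r") as fh:
        frame = pd.read_csv(fh, dtype={"subject_id": str})
    missing = [c for c in COVARIATE_HEADER if c not in frame.columns]
    if missing:
        raise CovariateFormatError(
            f"{path}: missing required column(s) {', '.join(missing)}"
        )
    records = []
    for row in frame.itertuples(index=False):
        records.append(
            SubjectRecord(
                subject_id=str(row.subject_id),
                age=float(row.age),
                bmi=float(row.bmi),
                illness_duration=float(row.illness_duration),
                edi2_total=float(row.edi2_total),
            )
        )
    return records


def write_covariates(records: list[SubjectRecord], path) -> None:
    """Write the subject covariate table; ``nan`` fields become empty cells."""
    with _open_text(path, "w") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(COVARIATE_HEADER)
        for rec in records:
            row = [rec.subject_id]
            for name in COVARIATE_HEADER[1:]:
                value = getattr(rec, name)
                row.append("" if math.isnan(value) else format(value, "g"))
            writer.writerow(row)
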