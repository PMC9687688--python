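"""Reading and writing Tappy-style keystroke logs and feature tables.

A Tappy log is a plain-text file with one keypress event per line and eight
whitespace-delimited columns::

    subject_id  date  time  region  hold_ms  transition  latency_ms  flight_ms

``region`` is the keyboard partition the pressed key belongs to -- left half
(L), right half (R) or the space bar (S) -- and ``transition`` is the ordered
pair of the previous and current regions (e.g. ``LR``).  The three timing
columns are the hold time (how long the key stayed down), the latency
(press-to-press interval) and the flight time (release-to-press interval),
all in milliseconds.
"""

from __future__ import annotations

import datetime as _dt
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "HEALTHY",
    "PARKINSON",
    "LABELS",
    "REGIONS",
    "TRANSITIONS",
    "KeystrokeEvent",
    "SubjectLog",
    "FeatureMatrix",
    "EmptyLogError",
    "ParseReport",
    "parse_log",
    "write_log",
    "read_feature_csv",
    "write_feature_csv",
]

HEALTHY = "healthy"
PARKINSON = "parkinson"
LABELS = (HEALTHY, PARKINSON)

REGIONS = ("L", "R", "S")
TRANSITIONS = tuple(a + b for a in REGIONS for b in REGIONS)

_DATE_FORMATS = ("%Y-%m-%d", "%y%m%d")
_TIME_FORMATS = ("%H:%M:%S.%f", "%H:%M:%S")


class EmptyLogError(ValueError):
    """Raised when a log file yields no valid keystroke events."""


@dataclass(frozen=True)
class KeystrokeEvent:
    """One parsed keypress record."""

    subject_id: str
    date: _dt.date
    time: _dt.time
    region: str
    hold_time: float
    transition: str
    latency: float
    flight: float

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValueError(f"region must be one of {REGIONS}, got {self.region!r}")
        if self.transition not in TRANSITIONS:
            raise ValueError(f"invalid transition {self.transition!r}")
        if self.transition[1] != self.region:
            raise ValueError(
                f"transition {self.transition!r} does not end in region {self.region!r}"
            )
        for name in ("hold_time", "latency", "flight"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")


@dataclass
class SubjectLog:
    """Ordered event stream for one subject, with a class label."""

    subject_id: str
    label: str
    events: list[KeystrokeEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")
        for ev in self.events:
            if ev.subject_id != self.subject_id:
                raise ValueError("all events must share the log's subject_id")
        stamps = [(ev.date, ev.time) for ev in self.events]
        if any(b < a for a, b in zip(stamps, stamps[1:])):
            raise ValueError("events must be non-decreasing in (date, time)")

    def __len__(self) -> int:
        return len(self.events)


@dataclass
class ParseReport:
    """Bookkeeping for a single parse_log call."""

    n_valid: int = 0
    n_skipped: int = 0
    skipped_lines: list[int] = field(default_factory=list)


@dataclass
class FeatureMatrix:
    """Per-subject feature vectors with a named column schema and labels.

    ``provenance`` distinguishes measured rows (``"real"``) from rows created
    by minority oversampling (``"synthetic"``).
    """

    values: np.ndarray
    column_names: list[str]
    labels: np.ndarray
    subject_ids: np.ndarray
    provenance: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        n, p = self.values.shape
        if len(self.column_names) != p:
            raise ValueError("column_names length must match values width")
        if len(set(self.column_names)) != p:
            raise ValueError("column names must be unique")
        self.labels = np.asarray(self.labels, dtype=object)
        self.subject_ids = np.asarray(self.subject_ids, dtype=object)
        if self.labels.shape != (n,) or self.subject_ids.shape != (n,):
            raise ValueError("labels and subject_ids must have one entry per row")
        if self.provenance is None:
            self.provenance = np.asarray(["real"] * n, dtype=object)
        else:
            self.provenance = np.asarray(self.provenance, dtype=object)
            if self.provenance.shape != (n,):
                raise ValueError("provenance must have one entry per row")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def class_counts(self) -> dict[str, int]:
        labels, counts = np.unique(self.labels.astype(str), return_counts=True)
        return dict(zip(labels.tolist(), counts.tolist()))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FeatureMatrix):
            return NotImplemented
        return (
            self.column_names == other.column_names
            and np.array_equal(self.values, other.values)
            and np.array_equal(self.labels, other.labels)
            and np.array_equal(self.subject_ids, other.subject_ids)
            and np.array_equal(self.provenance, other.provenance)
        )


def _parse_date(token: str) -> _dt.date:
    for fmt in _DATE_FORMATS:
        try:
            return _dt.datetime.strptime(token, fmt).date()
        except ValueError:
            continue
    raise ValueError(f"unparseable date {token!r}")


def _parse_time(token: str) -> _dt.time:
    for fmt in _TIME_FORMATS:
        try:
            return _dt.datetime.strptime(token, fmt).time()
        except ValueError:
            continue
    raise ValueError(f"unparseable time {token!r}")


def _parse_line(line: str) -> KeystrokeEvent:
    fields = line.split()
    if len(fields) != 8:
        raise ValueError(f"expected 8 fields, got {len(fields)}")
    sid, date_s, time_s, region, hold_s, transition, lat_s, fli_s = fields
    return KeystrokeEvent(
        subject_id=sid,
        date=_parse_date(date_s),
        time=_parse_time(time_s),
        region=region,
        hold_time=float(hold_s),
        transition=transition,
        latency=float(lat_s),
        flight=float(fli_s),
    )


def parse_log(
    path: str | Path,
    label: str,
    *,
    strict: bool = False,
    report: ParseReport | None = None,
) -> SubjectLog:
    """Parse a Tappy-style log file into a :class:`SubjectLog`.

    Lines that fail field validation are skipped and counted (real Tappy
    files contain occasional noise); ``strict=True`` raises on the first
    bad line instead.

    Parameters
    ----------
    path
        Log file with one 8-column event per line.
    label
        Class label for the subject, ``"healthy"`` or ``"parkinson"``.
    strict
        Abort on the first malformed line instead of skipping it.
    report
        Optional :class:`ParseReport` populated with valid/skipped counts.

    Raises
    ------
    EmptyLogError
        If the file contains no valid event lines.
    """
    path = Path(path)
    events: list[KeystrokeEvent] = []
    rep = report if report is not None else ParseReport()
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            try:
                events.append(_parse_line(line))
                rep.n_valid += 1
            except ValueError as exc:
                if strict:
                    raise ValueError(f"{path}:{lineno}: {exc}") from exc
                rep.n_skipped += 1
                rep.skipped_lines.append(lineno)
    if not events:
        raise EmptyLogError(f"no valid keystroke events in {path}")
    if rep.n_skipped:
        warnings.warn(
            f"{path}: skipped {rep.n_skipped} malformed line(s)", stacklevel=2
        )
    subject_id = events[0].subject_id
    return SubjectLog(subject_id=subject_id, label=label, events=events)


def write_log(log: SubjectLog, path: str | Path) -> Path:
    """Serialize a :class:`SubjectLog` as a tab-delimited Tappy-style file.

    The output is parseable by :func:`parse_log`; timing values keep full
    decimal precision.
    """
    if not log.events:
        raise ValueError("cannot write an empty log")
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for ev in log.events:
            time_s = ev.time.strftime("%H:%M:%S.%f")[:-3]  # millisecond resolution
            fh.write(
                f"{ev.subject_id}\t{ev.date.isoformat()}\t{time_s}\t{ev.region}\t"
                f"{ev.hold_time!r}\t{ev.transition}\t{ev.latency!r}\t{ev.flight!r}\n"
            )
    return path


_META_COLUMNS = ("subject_id", "label", "provenance")


def write_feature_csv(matrix: FeatureMatrix, path: str | Path) -> Path:
    """Write a :class:`FeatureMatrix` to CSV (metadata columns first)."""
    path = Path(path)
    df = pd.DataFrame(matrix.values, columns=matrix.column_names)
    for name, col in zip(_META_COLUMNS, (matrix.subject_ids, matrix.labels, matrix.provenance)):
        if name in matrix.column_names:
            raise ValueError(f"feature column name collides with metadata column {name!r}")
        df.insert(list(_META_COLUMNS).index(name), name, col)
    df.to_csv(path, index=False, float_format="%.12g")
    return path


def read_feature_csv(path: str | Path) -> FeatureMatrix:
    """Read a feature CSV written by :func:`write_feature_csv`."""
    df = pd.read_csv(str(path), dtype={c: str for c in _META_COLUMNS})
    missing = [c for c in _META_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"feature CSV missing metadata columns {missing}")
    feature_cols = [c for c in df.columns if c not in _META_COLUMNS]
    return FeatureMatrix(
        values=df[feature_cols].to_numpy(dtype=float),
        column_names=feature_cols,
        labels=df["label"].to_numpy(dtype=object),
        subject_ids=df["subject_id"].to_numpy(dtype=object),
        provenance=df["provenance"].to_numpy(dtype=object),
    )
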