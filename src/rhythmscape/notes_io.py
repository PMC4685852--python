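"""Data model and table I/O for detected note events.

The atomic record is a :class:`NoteEvent`: one detected sound with its onset
time (ms from the start of its recording file), its duration (ms), the serial
recording ID of the file it came from, and the bird's age in days post-hatch.
Events are grouped into :class:`Recording` objects (one per sound file, IDs
serial in developmental order) and those into a per-bird
:class:`DevelopmentDataset`, whose final recording day serves as the
crystallized adult reference for the proficiency analysis.

Tables are plain delimited text (TSV by default, CSV selectable), one header
row, one row per note.  Column names are remappable through a *dialect*
mapping so feature tables exported by external note-detection software can be
ingested without rewriting headers.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import EmptyDatasetError, FormatError, ParameterError

log = logging.getLogger(__name__)

#: canonical -> on-disk column names
CANONICAL_COLUMNS: dict[str, str] = {
    "bird_id": "bird_id",
    "recording_id": "recording_id",
    "day": "day",
    "onset": "onset_ms",
    "duration": "duration_ms",
    "timestamp": "timestamp",
    "label": "label",
}

MANDATORY_FIELDS = ("recording_id", "day", "onset", "duration")

#: noise filter bounds (ms): sounds shorter/longer than these are mostly noise
NOISE_MIN_DURATION = 15.0
NOISE_MAX_DURATION = 350.0


@dataclass(frozen=True)
class NoteEvent:
    """One detected note.

    ``onset`` and ``duration`` are milliseconds; ``timestamp`` is the
    wall-clock hour of day (0-24, hour resolution suffices); ``label`` is an
    optional note-type character.
    """

    recording_id: int
    day: int
    onset: float
    duration: float
    timestamp: float | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        if self.onset < 0:
            raise ParameterError(f"onset must be >= 0, got {self.onset}")
        if self.duration <= 0:
            raise ParameterError(f"duration must be > 0, got {self.duration}")


@dataclass
class Recording:
    """All notes of one sound file, sorted ascending by onset."""

    recording_id: int
    day: int
    events: list[NoteEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        for ev in self.events:
            if ev.recording_id != self.recording_id or ev.day != self.day:
                raise ParameterError(
                    "all events of a recording must share its recording_id and day"
                )
        self.events = sorted(self.events, key=lambda ev: ev.onset)

    @property
    def onsets(self) -> np.ndarray:
        return np.array([ev.onset for ev in self.events], dtype=float)

    @property
    def durations(self) -> np.ndarray:
        return np.array([ev.duration for ev in self.events], dtype=float)

    @property
    def hours(self) -> np.ndarray:
        """Wall-clock hours per event (NaN where absent)."""
        return np.array(
            [math.nan if ev.timestamp is None else ev.timestamp for ev in self.events],
            dtype=float,
        )

    def __len__(self) -> int:
        return len(self.events)


@dataclass
class DevelopmentDataset:
    """Per-bird collection of recordings spanning song development.

    ``final_day`` is the reference day of the crystallized adult rhythm; it
    defaults to the day of the last recording and may be overridden.
    """

    bird_id: str
    recordings: list[Recording] = field(default_factory=list)
    final_day: int | None = None

    def __post_init__(self) -> None:
        self.recordings = sorted(
            self.recordings, key=lambda r: (r.day, r.recording_id)
        )
        if self.final_day is None and self.recordings:
            self.final_day = self.recordings[-1].day

    @property
    def days(self) -> list[int]:
        """Distinct recording days, ascending."""
        return sorted({rec.day for rec in self.recordings})

    def recordings_on(self, day: int) -> list[Recording]:
        return [rec for rec in self.recordings if rec.day == day]

    @property
    def n_events(self) -> int:
        return sum(len(rec) for rec in self.recordings)

    def __len__(self) -> int:
        return len(self.recordings)


@dataclass
class LoadReport:
    """What happened while reading a note table."""

    rows_read: int
    rows_dropped: int
    n_recordings: int
    n_days: int

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(self.__dict__, indent=2)
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload


def _parse_timestamp(value) -> float | None:
    """Accept decimal hours, HH:MM[:SS] strings, or ISO-8601 datetimes."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, (int, float)):
        return float(value)
    text = str(value).strip()
    if not text or text.upper() in {"NA", "NAN"}:
        return None
    try:
        return float(text)
    except ValueError:
        pass
    ts = pd.to_datetime(text, errors="coerce")
    if ts is pd.NaT:
        raise ValueError(f"unparsable timestamp {text!r}")
    return float(ts.hour + ts.minute / 60.0 + ts.second / 3600.0)


def _resolve_sep(path: Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_note_table(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    sep: str | None = None,
    bird_id: str | None = None,
) -> tuple[DevelopmentDataset, LoadReport]:
    """Read a delimited note table into a validated dataset.

    Parameters
    ----------
    path
        Delimited text file with one header row (TSV default; ``.csv``
        extension or ``sep=','`` switches to comma).
    dialect
        Optional map from canonical field names (``recording_id``, ``day``,
        ``onset``, ``duration``, ``timestamp``, ``label``, ``bird_id``) to the
        column names actually present, overriding the defaults in
        :data:`CANONICAL_COLUMNS`.
    bird_id
        Overrides any ``bird_id`` column (first value otherwise; ``"unknown"``
        if absent).

    Returns
    -------
    (dataset, report)
        Rows whose mandatory numerics do not parse are dropped, not fatal;
        the drop count lands in the :class:`LoadReport`.

    Raises
    ------
    FormatError
        if a mandatory column cannot be resolved.
    EmptyDatasetError
        if the file contains no usable rows.
    """
    path = Path(path)
    columns = dict(CANONICAL_COLUMNS)
    if dialect:
        unknown = set(dialect) - set(columns)
        if unknown:
            raise FormatError(f"unknown dialect keys: {sorted(unknown)}")
        columns.update(dialect)

    try:
        frame = pd.read_csv(path, sep=_resolve_sep(path, sep), dtype=str)
    except pd.errors.EmptyDataError:
        raise EmptyDatasetError(f"{path} contains no rows")
    if frame.empty:
        raise EmptyDatasetError(f"{path} contains no rows")

    missing = [
        f for f in MANDATORY_FIELDS if columns[f] not in frame.columns
    ]
    if missing:
        raise FormatError(
            f"{path}: mandatory column(s) not found: "
            f"{[columns[f] for f in missing]} (have {list(frame.columns)})"
        )

    rows_read = len(frame)

    def to_float(series: pd.Series) -> pd.Series:
        # exact round-trip parse (pandas' fast path is not shortest-roundtrip)
        def conv(x):
            try:
                return float(x)
            except (TypeError, ValueError):
                return math.nan

        return series.map(conv)

    work = pd.DataFrame(
        {
            "recording_id": to_float(frame[columns["recording_id"]]),
            "day": to_float(frame[columns["day"]]),
            "onset": to_float(frame[columns["onset"]]),
            "duration": to_float(frame[columns["duration"]]),
        }
    )
    bad = (
        work[list(MANDATORY_FIELDS)].isna().any(axis=1)
        | (work["onset"] < 0)
        | (work["duration"] <= 0)
    )
    rows_dropped = int(bad.sum())
    if rows_dropped:
        log.warning("%s: dropped %d unparsable/invalid rows", path, rows_dropped)
    work = work[~bad]
    if work.empty:
        raise EmptyDatasetError(f"{path}: no valid rows after parsing")

    timestamps: list[float | None]
    if columns["timestamp"] in frame.columns:
        timestamps = [
            _parse_timestamp(v) for v in frame.loc[work.index, columns["timestamp"]]
        ]
    else:
        timestamps = [None] * len(work)
    if columns["label"] in frame.columns:
        raw_labels = frame.loc[work.index, columns["label"]]
        labels = [None if pd.isna(v) or str(v) == "" else str(v) for v in raw_labels]
    else:
        labels = [None] * len(work)

    if bird_id is None:
        if columns["bird_id"] in frame.columns:
            bird_id = str(frame[columns["bird_id"]].iloc[0])
        else:
            bird_id = "unknown"

    events_by_rec: dict[tuple[int, int], list[NoteEvent]] = {}
    for (rid, day, onset, duration), ts, label in zip(
        work.itertuples(index=False), timestamps, labels
    ):
        ev = NoteEvent(int(rid), int(day), float(onset), float(duration), ts, label)
        events_by_rec.setdefault((int(day), int(rid)), []).append(ev)

    recordings = [
        Recording(recording_id=rid, day=day, events=evs)
        for (day, rid), evs in sorted(events_by_rec.items())
    ]
    ds = DevelopmentDataset(bird_id=bird_id, recordings=recordings)
    report = LoadReport(
        rows_read=rows_read,
        rows_dropped=rows_dropped,
        n_recordings=len(recordings),
        n_days=len(ds.days),
    )
    return ds, report


def write_note_table(
    ds: DevelopmentDataset, path: str | Path, sep: str | None = None
) -> Path:
    """Write a dataset back to delimited text.

    ``read_note_table(write_note_table(ds))`` reproduces ``ds`` exactly
    (timestamps are written as decimal hours so floats round-trip).  An empty
    dataset yields a header-only file.  Optional columns are emitted only when
    at least one event carries them.
    """
    path = Path(path)
    rows = []
    for rec in ds.recordings:
        for ev in rec.events:
            rows.append(
                {
                    "bird_id": ds.bird_id,
                    "recording_id": ev.recording_id,
                    "day": ev.day,
                    "onset_ms": ev.onset,
                    "duration_ms": ev.duration,
                    "timestamp": ev.timestamp,
                    "label": ev.label,
                }
            )
    frame = pd.DataFrame(
        rows,
        columns=[
            "bird_id", "recording_id", "day", "onset_ms", "duration_ms",
            "timestamp", "label",
        ],
    )
    for optional in ("timestamp", "label"):
        if frame.empty or frame[optional].isna().all():
            frame = frame.drop(columns=[optional])
    # emit floats via repr (shortest round-trip) so read(write(ds)) is exact
    for col in ("onset_ms", "duration_ms", "timestamp"):
        if col in frame.columns and not frame.empty:
            frame[col] = frame[col].map(
                lambda v: "" if v is None or (isinstance(v, float) and math.isnan(v))
                else repr(float(v))
            )
    frame.to_csv(path, sep=_resolve_sep(path, sep), index=False)
    return path


def filter_notes(
    ds: DevelopmentDataset,
    min_dur: float = NOISE_MIN_DURATION,
    max_dur: float = NOISE_MAX_DURATION,
) -> tuple[DevelopmentDataset, int]:
    """Remove noise notes by duration before interval analysis.

    Detected sounds shorter than ``min_dur`` or longer than ``max_dur``
    (defaults 15 and 350 ms, both bounds inclusive for keeping) are mostly
    noise; removing them improves the accuracy of inter-onset-interval
    measurement.  Recording structure is preserved: recordings emptied by the
    filter are retained with zero events.

    Returns the filtered copy and the number of events removed.
    """
    if not (0 <= min_dur < max_dur):
        raise ParameterError(
            f"require 0 <= min_dur < max_dur, got ({min_dur}, {max_dur})"
        )
    removed = 0
    recordings = []
    for rec in ds.recordings:
        kept = [ev for ev in rec.events if min_dur <= ev.duration <= max_dur]
        removed += len(rec.events) - len(kept)
        recordings.append(Recording(rec.recording_id, rec.day, kept))
    if removed and all(len(r) == 0 for r in recordings):
        log.warning("filter_notes removed every event (%d)", removed)
    out = DevelopmentDataset(
        bird_id=ds.bird_id, recordings=recordings, final_day=ds.final_day
    )
    return out, removed
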