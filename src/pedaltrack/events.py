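"""Revolution event streams and their CSV serialization.

A pedal desk records one timestamped observation per pedal revolution: a
magnet on the flywheel closes a switch once per crank turn and the desk
stores ``(subject, device, timestamp)``.  This module defines the in-memory
containers for such streams and a plain-text round-trip format
(``subject_id,device_id,timestamp`` with ISO-8601 millisecond timestamps).

Internally a stream keeps an absolute millisecond epoch plus event times as
float seconds since that epoch, which is what the tracker and aggregation
code operate on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Default absolute origin for simulated streams (arbitrary office morning).
DEFAULT_EPOCH = np.datetime64("2015-06-01T09:00:00.000", "ms")

CSV_COLUMNS = ("subject_id", "device_id", "timestamp")


class EventParseError(ValueError):
    """A CSV row could not be parsed (reported with its 1-based line number)."""


class StreamValidationError(ValueError):
    """An event stream violates ordering/uniqueness invariants."""


@dataclass(frozen=True)
class RevolutionEvent:
    """One recorded pedal revolution from one device."""

    device_id: str
    subject_id: str
    timestamp: np.datetime64  # millisecond resolution


@dataclass
class EventStream:
    """Ordered revolutions for one (subject, device) pair.

    Parameters
    ----------
    times
        Event times in float seconds since `epoch`, strictly increasing.
    epoch
        Absolute millisecond timestamp of time zero for this stream.
    """

    subject_id: str
    device_id: str
    times: np.ndarray = field(default_factory=lambda: np.empty(0))
    epoch: np.datetime64 = DEFAULT_EPOCH

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if t.ndim != 1:
            raise StreamValidationError("event times must be one-dimensional")
        if t.size and not np.all(np.isfinite(t)):
            raise StreamValidationError(
                f"stream ({self.subject_id}, {self.device_id}): non-finite event time"
            )
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise StreamValidationError(
                f"stream ({self.subject_id}, {self.device_id}): timestamps must be "
                "strictly increasing (duplicates indicate corrupt input)"
            )
        self.times = t
        self.epoch = np.datetime64(self.epoch, "ms")

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def timestamps(self) -> np.ndarray:
        """Absolute event timestamps as ``datetime64[ms]`` (rounded to 1 ms)."""
        ms = self.epoch.astype("int64") + np.rint(self.times * 1000.0).astype("int64")
        return ms.astype("datetime64[ms]")

    @property
    def abs_seconds(self) -> np.ndarray:
        """Event times in float seconds since the Unix epoch."""
        return self.epoch.astype("int64") / 1000.0 + self.times

    @property
    def events(self) -> tuple[RevolutionEvent, ...]:
        return tuple(
            RevolutionEvent(self.device_id, self.subject_id, ts)
            for ts in self.timestamps
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EventStream):
            return NotImplemented
        return (
            self.subject_id == other.subject_id
            and self.device_id == other.device_id
            and len(self) == len(other)
            and bool(np.array_equal(self.timestamps, other.timestamps))
        )

    @classmethod
    def from_timestamps(
        cls, subject_id: str, device_id: str, timestamps: Sequence | np.ndarray
    ) -> "EventStream":
        """Build a stream from absolute timestamps; epoch is the first event."""
        ts = np.asarray(timestamps, dtype="datetime64[ms]")
        if ts.size == 0:
            return cls(subject_id, device_id, np.empty(0), DEFAULT_EPOCH)
        epoch = ts[0]
        times = (ts - epoch) / np.timedelta64(1, "ms") / 1000.0
        return cls(subject_id, device_id, times, epoch)


def read_events(path) -> list[EventStream]:
    """Read an events CSV into one :class:`EventStream` per (subject, device).

    Rows may arrive in any order; each stream is sorted by timestamp so the
    result is deterministic.  Duplicate timestamps within a stream are
    rejected — a magnet switch cannot fire twice at the same instant.

    Raises
    ------
    EventParseError
        If a timestamp cannot be parsed (the message names the CSV line).
    StreamValidationError
        If a stream contains duplicate timestamps.
    """
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise EventParseError(f"{path}: missing column(s) {missing}")
    if df.empty:
        logger.info("read 0 revolution rows (0 streams) from %s", path)
        return []
    parsed = pd.to_datetime(df["timestamp"], format="ISO8601", errors="coerce")
    if parsed.isna().any():
        i = int(np.flatnonzero(parsed.isna().to_numpy())[0])
        # +2: one for the header row, one for 1-based numbering
        raise EventParseError(
            f"{path}, line {i + 2}: malformed timestamp {df['timestamp'].iloc[i]!r}"
        )
    df = df.assign(_ts=parsed.to_numpy().astype("datetime64[ms]"))
    streams: list[EventStream] = []
    for (subj, dev), group in df.groupby(["subject_id", "device_id"], sort=True):
        ts = np.sort(group["_ts"].to_numpy())
        if ts.size > 1 and np.any(np.diff(ts) == np.timedelta64(0, "ms")):
            raise StreamValidationError(
                f"stream ({subj}, {dev}): duplicate timestamps in {path}"
            )
        streams.append(EventStream.from_timestamps(str(subj), str(dev), ts))
    logger.info(
        "read %d revolution rows (%d streams) from %s", len(df), len(streams), path
    )
    return streams


def write_events(streams: Iterable[EventStream], path) -> None:
    """Write streams to CSV; ``read_events`` round-trips to the millisecond."""
    rows = []
    for s in streams:
        stamps = np.datetime_as_string(s.timestamps, unit="ms")
        for stamp in stamps:
            rows.append((s.subject_id, s.device_id, stamp))
    out = pd.DataFrame(rows, columns=list(CSV_COLUMNS))
    out.to_csv(path, index=False)
    logger.info("wrote %d revolution rows to %s", len(out), path)
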