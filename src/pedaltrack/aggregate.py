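"""Resampling event streams to second / minute / trial RPM series.

Criterion and test devices are compared on a common per-second grid: each
whole (absolute) second that contains at least one rated revolution gets the
mean instantaneous RPM of those revolutions; quiet seconds inherit the last
value while the elapsed gap stays under the bout threshold, and go missing
afterwards.  Seconds average to minutes (with a minimum-coverage rule for
partial minutes), minutes average — unweighted — to a trial value, and two
series merge on matched timestamps by inner join.

``observed_minute_counts`` is the direct-observation oracle: the number of
crank revolutions counted in each successive 60 s window, as a human scoring
video would tally them.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .events import EventStream
from .tracker import GAP_THRESHOLD_S

logger = logging.getLogger(__name__)

RESOLUTIONS = ("second", "minute", "trial")


@dataclass
class RpmSeries:
    """Cadence samples for one device at one resolution.

    ``times`` are integer grid indices — absolute seconds since the Unix
    epoch at second resolution, absolute minutes at minute resolution —
    so that two devices observing the same session share a grid.
    """

    subject_id: str
    device_id: str
    resolution: str
    times: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    values: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        if self.resolution not in RESOLUTIONS:
            raise ValueError(f"unknown resolution {self.resolution!r}")
        self.times = np.asarray(self.times, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("series times must be strictly increasing")
        if np.any(self.values < 0):
            raise ValueError("rpm values must be non-negative")

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass
class PairedSeries:
    """Time-aligned criterion/test cadence values for one subject."""

    subject_id: str
    resolution: str
    times: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    criterion: np.ndarray = field(default_factory=lambda: np.empty(0))
    test: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.int64)
        self.criterion = np.asarray(self.criterion, dtype=float)
        self.test = np.asarray(self.test, dtype=float)
        if not (self.times.size == self.criterion.size == self.test.size):
            raise ValueError("paired series arrays must have equal length")

    def __len__(self) -> int:
        return int(self.times.size)


def events_to_seconds(
    stream: EventStream, gap_threshold: float = GAP_THRESHOLD_S
) -> RpmSeries:
    """Per-second cadence from a revolution stream.

    A revolution is *rated* when the gap to the preceding revolution is under
    ``gap_threshold`` (bout-opening events carry no cadence).  Each second
    holding rated events gets their mean instantaneous RPM.  Event-free
    seconds inherit the last second's value while the time since the last
    revolution stays under the threshold; a bout-opening event resets the
    carried value.
    """
    if len(stream) == 0:
        return RpmSeries(stream.subject_id, stream.device_id, "second")
    abs_t = stream.abs_seconds
    gaps = np.diff(abs_t)
    # rpm[i] for event i>=1 when its gap is inside a bout, else NaN
    rpm = np.full(abs_t.size, np.nan)
    rated = gaps < gap_threshold
    rpm[1:][rated] = 60.0 / gaps[rated]

    secs = np.floor(abs_t).astype(np.int64)
    first, last = int(secs[0]), int(secs[-1])
    by_sec: dict[int, list[int]] = {}
    for i, s in enumerate(secs):
        by_sec.setdefault(int(s), []).append(i)

    out_t: list[int] = []
    out_v: list[float] = []
    carry_value: float | None = None
    last_event_t: float | None = None
    for sec in range(first, last + 1):
        idx = by_sec.get(sec)
        if idx is not None:
            rates = [rpm[i] for i in idx if not math.isnan(rpm[i])]
            if rates:
                carry_value = float(np.mean(rates))
                out_t.append(sec)
                out_v.append(carry_value)
            else:
                carry_value = None  # bout boundary: nothing to carry yet
            last_event_t = float(abs_t[idx[-1]])
        elif (
            carry_value is not None
            and last_event_t is not None
            and sec - last_event_t < gap_threshold
        ):
            out_t.append(sec)
            out_v.append(carry_value)
    return RpmSeries(
        stream.subject_id, stream.device_id, "second", np.array(out_t), np.array(out_v)
    )


def seconds_to_minutes(series: RpmSeries, min_coverage: float = 0.8) -> RpmSeries:
    """Average per-second cadence into whole minutes.

    Minutes covering less than ``min_coverage`` of their 60 seconds (missing
    seconds included) are dropped, so ragged trial edges do not produce
    unstable means.
    """
    if series.resolution != "second":
        raise ValueError(f"expected second-resolution input, got {series.resolution}")
    if len(series) == 0:
        return RpmSeries(series.subject_id, series.device_id, "minute")
    minutes = series.times // 60
    out_t, out_v = [], []
    for m in np.unique(minutes):
        sel = minutes == m
        if int(sel.sum()) / 60.0 >= min_coverage:
            out_t.append(int(m))
            out_v.append(float(series.values[sel].mean()))
    return RpmSeries(
        series.subject_id, series.device_id, "minute", np.array(out_t), np.array(out_v)
    )


def minutes_to_trial(series: RpmSeries) -> RpmSeries:
    """Unweighted mean of minute values: one trial-level sample."""
    if series.resolution != "minute":
        raise ValueError(f"expected minute-resolution input, got {series.resolution}")
    if len(series) == 0:
        raise ValueError("cannot summarize an empty minute series to trial level")
    return RpmSeries(
        series.subject_id,
        series.device_id,
        "trial",
        np.array([series.times[0]]),
        np.array([float(series.values.mean())]),
    )


def align(criterion: RpmSeries, test: RpmSeries) -> PairedSeries:
    """Inner-join two same-subject, same-resolution series on timestamps."""
    if criterion.resolution != test.resolution:
        raise ValueError(
            f"resolution mismatch: {criterion.resolution} vs {test.resolution}"
        )
    if criterion.subject_id != test.subject_id:
        raise ValueError(
            f"subject mismatch: {criterion.subject_id} vs {test.subject_id}"
        )
    common, ic, it = np.intersect1d(criterion.times, test.times, return_indices=True)
    dropped = (len(criterion) - common.size) + (len(test) - common.size)
    if common.size == 0:
        logger.warning(
            "subject %s: no matched timestamps between %s and %s",
            criterion.subject_id, criterion.device_id, test.device_id,
        )
    else:
        logger.info(
            "subject %s: aligned %d samples (%d unmatched dropped)",
            criterion.subject_id, common.size, dropped,
        )
    return PairedSeries(
        subject_id=criterion.subject_id,
        resolution=criterion.resolution,
        times=common,
        criterion=criterion.values[ic],
        test=test.values[it],
    )


def observed_minute_counts(
    stream: EventStream, trial_start: float | None = None
) -> np.ndarray:
    """Revolutions counted in each successive 60 s window from trial start.

    Windows are ``[trial_start + 60k, trial_start + 60(k+1))`` in stream
    seconds; this is the direct-observation ground-truth tally.
    """
    if len(stream) == 0:
        return np.empty(0, dtype=np.int64)
    t = stream.times
    start = float(t[0]) if trial_start is None else float(trial_start)
    if start > t[0]:
        raise ValueError("trial_start must not be after the first event")
    win = np.floor((t - start) / 60.0).astype(np.int64)
    return np.bincount(win, minlength=int(win[-1]) + 1).astype(np.int64)
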