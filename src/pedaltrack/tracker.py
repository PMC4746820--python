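"""The pedal-desk tracker computation.

The desk's tracker turns a stream of revolution timestamps into the
quantities a user sees:

* instantaneous cadence, ``RPM = 60 / lapsed_time`` between consecutive
  revolutions;
* a real-time running total of pedaling duration, accumulating each lapsed
  time that is strictly below 15 s;
* bouts — maximal runs of revolutions in which every inter-revolution gap is
  below 15 s (a gap of 15 s or more splits);
* interval summaries — total bout duration in minutes, total revolution
  count, and mean RPM = revolutions / duration;
* an estimated mechanical power from the fixed flywheel resistance.

The summary's mean RPM follows the tracker's literal counting rule, which
includes each bout's first revolution in the numerator; for a single bout of
``n`` events at constant gap Δ this gives ``(n/(n-1))·(60/Δ)``, a small
upward bias that vanishes as bouts grow.  ``count_mode="interval"`` exposes
the unbiased alternative (count revolutions after each bout's first).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .events import DEFAULT_EPOCH, EventStream, StreamValidationError

#: A pause of this many seconds (or more) ends a bout.
GAP_THRESHOLD_S = 15.0

STANDARD_GRAVITY = 9.80665  # m/s^2; 1 kilopond = 1 kg * g newtons

_INTERVAL_FREQ = {"daily": "D", "weekly": "W-SUN", "monthly": "M"}


def instantaneous_rpm(lapsed_time: float) -> float:
    """Cadence implied by the time between two consecutive revolutions."""
    if not lapsed_time > 0:
        raise ValueError(f"lapsed_time must be > 0, got {lapsed_time}")
    return 60.0 / lapsed_time


@dataclass(frozen=True)
class TrackerState:
    """Real-time tracker display state (running duration is non-decreasing)."""

    running_duration: float = 0.0  # seconds
    last_event_time: float | None = None
    current_rpm: float | None = None


def update_tracker(
    state: TrackerState, event_time: float, gap_threshold: float = GAP_THRESHOLD_S
) -> TrackerState:
    """Fold one revolution event into the running-total display.

    The lapsed time since the previous revolution is added to the running
    duration only while it is strictly below the gap threshold; longer gaps
    leave the totals untouched (the user stopped pedaling).
    """
    if state.last_event_time is None:
        return replace(state, last_event_time=float(event_time))
    lapsed = float(event_time) - state.last_event_time
    if lapsed <= 0:
        raise StreamValidationError(
            f"event time {event_time} not after previous {state.last_event_time}"
        )
    if lapsed < gap_threshold:
        return TrackerState(
            running_duration=state.running_duration + lapsed,
            last_event_time=float(event_time),
            current_rpm=instantaneous_rpm(lapsed),
        )
    return replace(state, last_event_time=float(event_time))


@dataclass(frozen=True)
class Bout:
    """A maximal run of revolutions with every inter-event gap < 15 s."""

    start: float
    end: float
    n_revolutions: int

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("bout end before start")
        if self.n_revolutions < 1:
            raise ValueError("a bout contains at least one revolution")


def bout_duration(bout: Bout) -> float:
    """Ending timestamp − starting timestamp, in seconds."""
    return bout.end - bout.start


def segment_bouts(
    stream: EventStream | Sequence[float] | np.ndarray,
    gap_threshold: float = GAP_THRESHOLD_S,
) -> list[Bout]:
    """Split a sorted event stream into bouts at gaps ≥ ``gap_threshold``.

    Every event belongs to exactly one bout; a single event forms a
    zero-duration bout of one revolution.
    """
    times = stream.times if isinstance(stream, EventStream) else np.asarray(stream, float)
    if times.size == 0:
        return []
    cuts = np.flatnonzero(np.diff(times) >= gap_threshold) + 1
    return [
        Bout(start=float(seg[0]), end=float(seg[-1]), n_revolutions=int(seg.size))
        for seg in np.split(times, cuts)
    ]


@dataclass(frozen=True)
class UsageSummary:
    """Duration and mean cadence over one reporting interval.

    ``mean_rpm`` is ``None`` (never a silent NaN) when the interval holds no
    positive-duration bouts.
    """

    interval: str  # session | daily | weekly | monthly
    total_duration_min: float
    total_revolutions: int
    mean_rpm: float | None
    interval_start: np.datetime64 | None = None


def summarize_usage(
    bouts: Iterable[Bout],
    interval: str = "session",
    count_mode: str = "literal",
    interval_start: np.datetime64 | None = None,
) -> UsageSummary:
    """Three-step interval summary: bout durations, counts, count/duration.

    ``count_mode="literal"`` counts every observation in each bout (the
    tracker's rule); ``"interval"`` counts revolutions after each bout's
    first, which makes the ratio an unbiased cadence.
    """
    if count_mode not in ("literal", "interval"):
        raise ValueError(f"unknown count_mode {count_mode!r}")
    bouts = list(bouts)
    duration_min = sum(bout_duration(b) for b in bouts) / 60.0
    if count_mode == "literal":
        revolutions = sum(b.n_revolutions for b in bouts)
    else:
        revolutions = sum(b.n_revolutions - 1 for b in bouts)
    mean_rpm = revolutions / duration_min if duration_min > 0 else None
    return UsageSummary(
        interval=interval,
        total_duration_min=duration_min,
        total_revolutions=revolutions,
        mean_rpm=mean_rpm,
        interval_start=interval_start,
    )


def summarize_stream(
    stream: EventStream,
    interval: str = "session",
    gap_threshold: float = GAP_THRESHOLD_S,
    count_mode: str = "literal",
) -> list[UsageSummary]:
    """Segment a stream into bouts and summarize per calendar interval.

    Intervals are calendar-aligned on the stream's local clock (weeks start
    Monday); a bout spanning a boundary is assigned wholly to the interval
    containing its start.
    """
    bouts = segment_bouts(stream, gap_threshold)
    if interval == "session":
        start = stream.timestamps[0] if len(stream) else None
        return [summarize_usage(bouts, "session", count_mode, start)]
    if interval not in _INTERVAL_FREQ:
        raise ValueError(f"unknown interval {interval!r}")
    freq = _INTERVAL_FREQ[interval]
    epoch_s = stream.epoch.astype("int64") / 1000.0
    grouped: dict[pd.Period, list[Bout]] = {}
    for b in bouts:
        period = pd.Timestamp((epoch_s + b.start) * 1e9).to_period(freq)
        grouped.setdefault(period, []).append(b)
    return [
        summarize_usage(
            grouped[p], interval, count_mode, np.datetime64(p.start_time, "ms")
        )
        for p in sorted(grouped)
    ]


@dataclass(frozen=True)
class FlywheelModel:
    """Fixed magnetic-brake flywheel: force in kiloponds, belt travel per crank turn.

    The desk's brake is not adjustable; its ≈0.30 kp resistance keeps power
    in the very-light range.  Belt travel per crank revolution is not a
    published spec of the desk; the 8.15 m default places 30–90 RPM at
    12–36 W.
    """

    resistance_kp: float = 0.30
    travel_per_rev_m: float = 8.15
    g: float = STANDARD_GRAVITY

    def __post_init__(self) -> None:
        if self.resistance_kp <= 0 or self.travel_per_rev_m <= 0:
            raise ValueError("resistance and travel per revolution must be positive")


def estimate_power(rpm: float, model: FlywheelModel = FlywheelModel()) -> float:
    """Mechanical power in watts: braking force × flywheel belt speed.

    ``P = resistance·g × travel_per_rev × rpm / 60`` — exactly linear in rpm.
    """
    if rpm < 0:
        raise ValueError(f"rpm must be non-negative, got {rpm}")
    force_n = model.resistance_kp * model.g
    speed_m_s = model.travel_per_rev_m * rpm / 60.0
    return force_n * speed_m_s
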