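"""Synthetic pedaling sessions and device-error models.

The generator stands in for a human validation trial: office workers pedal
a desk at a self-selected pace for roughly 20 minutes while two devices —
a near-perfect criterion cadence sensor and the desk's magnet-switch
counter — log every revolution.

Ground truth
    Each subject's cadence follows a per-second AR(1) around a subject mean
    (population mean 55 RPM, between-subject SD 11 RPM, truncated to
    30–90 RPM), floored at 20 RPM, with optional pauses.  Revolution ``i+1``
    occurs ``60 / c(t_i)`` seconds after revolution ``i``.

Device errors
    A device may drop revolutions (``miss_prob``), double-fire — the extra
    event lands midway to the next revolution (``extra_prob``) — jitter
    timestamps (``timestamp_jitter_sd``), or run a small multiplicative
    cadence bias (``rate_scale``, realized as uniform time compression).
    The ``desk_like`` preset carries a +1.8 % cadence bias and 5 ms jitter,
    reproducing a magnet counter that slightly overestimates cadence; the
    ``garmin_like`` preset is jitter-only.

Everything is reproducible from one master seed: subject ``i`` draws from
``SeedSequence([master, i])`` and device ``k`` of subject ``i`` from
``SeedSequence([master, i, k])``, so any subset regenerates independently.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .events import DEFAULT_EPOCH, EventStream, write_events

logger = logging.getLogger(__name__)

CADENCE_FLOOR_RPM = 20.0

#: Population distribution of self-selected cadence across subjects.
POPULATION_MEAN_RPM = 55.0
POPULATION_SD_RPM = 11.0
POPULATION_RANGE_RPM = (30.0, 90.0)


@dataclass(frozen=True)
class CadenceProfile:
    """Within-subject cadence dynamics for one session."""

    subject_mean: float = POPULATION_MEAN_RPM  # RPM
    within_sd: float = 3.0  # stationary SD of the AR(1), RPM
    ar_coefficient: float = 0.95  # per-second autocorrelation
    pause_rate: float = 0.0  # pauses per minute (guided desk work: none)
    pause_duration_range: tuple[float, float] = (20.0, 45.0)  # seconds

    def __post_init__(self) -> None:
        if not POPULATION_RANGE_RPM[0] <= self.subject_mean <= POPULATION_RANGE_RPM[1]:
            raise ValueError("subject_mean outside the plausible 30–90 RPM range")
        if self.within_sd < 0 or not 0 <= self.ar_coefficient < 1:
            raise ValueError("need within_sd ≥ 0 and 0 ≤ ar_coefficient < 1")


@dataclass(frozen=True)
class DeviceErrorModel:
    """Phenomenological error model applied to a truth stream."""

    kind: str = "perfect"  # perfect | jitter | miss | extra | compound
    timestamp_jitter_sd: float = 0.0  # seconds
    miss_prob: float = 0.0  # per revolution
    extra_prob: float = 0.0  # per revolution
    rate_scale: float = 1.0  # multiplicative cadence bias (>1: overestimates)

    def __post_init__(self) -> None:
        for p in (self.miss_prob, self.extra_prob):
            if not 0 <= p < 1:
                raise ValueError("probabilities must be in [0, 1)")
        if self.timestamp_jitter_sd < 0 or self.rate_scale <= 0:
            raise ValueError("jitter SD must be ≥ 0 and rate_scale > 0")


_PRESETS = {
    "perfect": DeviceErrorModel(kind="perfect"),
    "garmin_like": DeviceErrorModel(kind="jitter", timestamp_jitter_sd=0.020),
    "desk_like": DeviceErrorModel(
        kind="compound", timestamp_jitter_sd=0.005, rate_scale=1.018
    ),
}


def device_preset(name: str) -> DeviceErrorModel:
    """Named error models: ``perfect``, ``garmin_like``, ``desk_like``."""
    try:
        return _PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown device preset {name!r}; choose from {sorted(_PRESETS)}"
        ) from None


@dataclass(frozen=True)
class StudyDesign:
    """Shape of the simulated validation trial."""

    n_subjects: int = 41
    trial_duration_mean: float = 20.5  # minutes
    trial_duration_sd: float = 2.5  # minutes
    min_duration: float = 5.0  # minutes, truncation floor
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("need at least one subject")
        if self.trial_duration_mean <= 0 or self.trial_duration_sd < 0:
            raise ValueError("durations must be positive")


def simulate_truth(
    profile: CadenceProfile,
    duration: float,
    seed: int | np.random.Generator,
    subject_id: str = "S01",
    device_id: str = "truth",
    epoch: np.datetime64 = DEFAULT_EPOCH,
) -> EventStream:
    """Generate one subject's true revolution stream.

    ``duration`` is in minutes.  With ``within_sd = 0`` and no pauses the
    stream is exactly periodic at ``60 / subject_mean`` seconds.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    duration_s = float(duration) * 60.0
    if duration_s <= 0:
        return EventStream(subject_id, device_id, np.empty(0), epoch)

    n_sec = int(np.ceil(duration_s)) + 1
    phi, sd = profile.ar_coefficient, profile.within_sd
    innov_sd = sd * np.sqrt(1.0 - phi**2)
    dev = np.empty(n_sec)
    dev[0] = rng.normal(0.0, sd) if sd > 0 else 0.0
    shocks = rng.normal(0.0, innov_sd, n_sec - 1) if sd > 0 else np.zeros(n_sec - 1)
    for s in range(1, n_sec):
        dev[s] = phi * dev[s - 1] + shocks[s - 1]
    cadence = np.maximum(profile.subject_mean + dev, CADENCE_FLOOR_RPM)

    n_pauses = rng.poisson(profile.pause_rate * duration) if profile.pause_rate > 0 else 0
    pause_at = np.sort(rng.uniform(0.0, duration_s, n_pauses)) if n_pauses else np.empty(0)
    lo, hi = profile.pause_duration_range
    pause_len = rng.uniform(lo, hi, n_pauses) if n_pauses else np.empty(0)

    times: list[float] = []
    t = 0.0
    next_pause = 0
    while t <= duration_s:
        times.append(t)
        while next_pause < n_pauses and t >= pause_at[next_pause]:
            t += float(pause_len[next_pause])
            next_pause += 1
        t += 60.0 / cadence[min(int(t), n_sec - 1)]
    return EventStream(subject_id, device_id, np.asarray(times), epoch)


def apply_device(
    truth: EventStream,
    model: DeviceErrorModel,
    seed: int | np.random.Generator,
    device_id: str | None = None,
) -> EventStream:
    """Pass a truth stream through a device error model.

    Order of corruption: misses, double-fires (duplicate midway to the next
    event), rate bias (time compression), then timestamp jitter; the result
    is re-sorted and kept strictly increasing.  A ``perfect`` model is the
    identity.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dev_id = device_id or model.kind
    t = truth.times.copy()
    if t.size:
        if model.miss_prob > 0:
            t = t[rng.random(t.size) >= model.miss_prob]
        if model.extra_prob > 0 and t.size > 1:
            dup = rng.random(t.size - 1) < model.extra_prob
            extras = (t[:-1][dup] + t[1:][dup]) / 2.0
            t = np.sort(np.concatenate([t, extras]))
        if model.rate_scale != 1.0:
            t = t / model.rate_scale
        if model.timestamp_jitter_sd > 0:
            t = np.sort(t + rng.normal(0.0, model.timestamp_jitter_sd, t.size))
        # enforce strict ordering after perturbation (ms-scale nudges only)
        for i in range(1, t.size):
            if t[i] <= t[i - 1]:
                t[i] = t[i - 1] + 1e-6
    return EventStream(truth.subject_id, dev_id, t, truth.epoch)


@dataclass
class StudyData:
    """Simulated trial: per-subject truth plus two observed streams."""

    truth: list[EventStream]
    criterion: list[EventStream]
    test: list[EventStream]
    ledger: dict


def simulate_study(
    design: StudyDesign = StudyDesign(),
    criterion_model: DeviceErrorModel = _PRESETS["garmin_like"],
    test_model: DeviceErrorModel = _PRESETS["desk_like"],
    profile: CadenceProfile = CadenceProfile(),
) -> StudyData:
    """Simulate the full paired-device trial.

    Each subject draws a mean cadence from the truncated population normal
    and a trial duration from Normal(trial_duration_mean, trial_duration_sd)
    truncated above ``min_duration``; ``profile`` supplies the within-subject
    dynamics.  The ledger records every generating parameter so recovery
    tests can compare estimates against them.
    """
    truth, criterion, test = [], [], []
    subjects = []
    width = max(2, len(str(design.n_subjects)))
    lo, hi = POPULATION_RANGE_RPM
    for i in range(design.n_subjects):
        rng = np.random.default_rng(np.random.SeedSequence([design.seed, i]))
        mean = float(rng.normal(POPULATION_MEAN_RPM, POPULATION_SD_RPM))
        while not lo <= mean <= hi:
            mean = float(rng.normal(POPULATION_MEAN_RPM, POPULATION_SD_RPM))
        dur = float(rng.normal(design.trial_duration_mean, design.trial_duration_sd))
        while dur <= design.min_duration:
            dur = float(rng.normal(design.trial_duration_mean, design.trial_duration_sd))
        subj = f"S{i + 1:0{width}d}"
        prof = replace(profile, subject_mean=mean)
        tr = simulate_truth(prof, dur, rng, subject_id=subj)
        truth.append(tr)
        criterion.append(
            apply_device(
                tr, criterion_model,
                np.random.default_rng(np.random.SeedSequence([design.seed, i, 1])),
                device_id="criterion",
            )
        )
        test.append(
            apply_device(
                tr, test_model,
                np.random.default_rng(np.random.SeedSequence([design.seed, i, 2])),
                device_id="test",
            )
        )
        subjects.append(
            {
                "subject_id": subj,
                "mean_rpm": mean,
                "duration_min": dur,
                "n_revolutions": len(tr),
            }
        )
    ledger = {
        "design": dataclasses.asdict(design),
        "profile": dataclasses.asdict(profile),
        "criterion_model": dataclasses.asdict(criterion_model),
        "test_model": dataclasses.asdict(test_model),
        "population": {
            "mean_rpm": POPULATION_MEAN_RPM,
            "sd_rpm": POPULATION_SD_RPM,
            "range_rpm": list(POPULATION_RANGE_RPM),
        },
        "subjects": subjects,
    }
    logger.info(
        "simulated %d subjects (%d truth revolutions)",
        design.n_subjects, sum(len(s) for s in truth),
    )
    return StudyData(truth=truth, criterion=criterion, test=test, ledger=ledger)


def write_study(study: StudyData, outdir: str | Path) -> None:
    """Write truth/criterion/test events CSVs plus the generating ledger."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_events(study.truth, outdir / "truth.csv")
    write_events(study.criterion, outdir / "criterion.csv")
    write_events(study.test, outdir / "test.csv")
    with open(outdir / "ledger.json", "w") as fh:
        json.dump(study.ledger, fh, indent=2)
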