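import numpy as np
import pytest

from pedaltrack import (
    CadenceProfile,
    EventStream,
    StudyDesign,
    simulate_study,
    simulate_truth,
)


def make_stream(times, subject="S01", device="dev"):
    return EventStream(subject, device, np.asarray(times, dtype=float))


@pytest.fixture(scope="session")
def steady_stream():
    """Constant 60 RPM for one minute: events exactly 1 s apart."""
    return simulate_truth(
        CadenceProfile(subject_mean=60.0, within_sd=0.0), 1.0, seed=0
    )


@pytest.fixture(scope="session")
def small_study():
    """A 5-subject paired-device trial with the default error presets."""
    return simulate_study(StudyDesign(n_subjects=5, seed=11))
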