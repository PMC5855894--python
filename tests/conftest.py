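"""Shared fixtures: synthetic subjects, sessions and epochs.

Everything is generated programmatically at collection time from fixed
seeds; session-scoped fixtures are reused across test modules to keep the
suite fast.
"""

import numpy as np
import pytest

import neuroauth as na


@pytest.fixture(scope="session")
def profile() -> na.SubjectProfile:
    return na.make_subject("A", seed=1)


@pytest.fixture(scope="session")
def other_profile() -> na.SubjectProfile:
    return na.make_subject("B", seed=2)


@pytest.fixture(scope="session")
def session_600() -> tuple:
    """One 600 Hz RSVP session (200 stimuli, pink noise) plus its events."""
    prof = na.make_subject("A", seed=1)
    spec = na.SessionSpec(n_trials=200, noise_sd=1.5, sample_rate=600.0,
                          seed=3)
    return na.gen_eeg_session(prof, spec)


@pytest.fixture(scope="session")
def epochs(session_600) -> na.EpochSet:
    rec, events = session_600
    return na.epoch_and_baseline(na.lowpass_eeg(rec), events)


@pytest.fixture(scope="session")
def clean_blink(profile) -> na.BlinkWaveform:
    """One noise-free blink, detected and normalized from a raw trace."""
    rec = na.gen_blink_session(profile, 1, noise_sd=0.0, seed=5, rate=600.0)
    blinks = na.normalize_blinks(na.detect_blinks(rec))
    assert len(blinks) == 1
    return blinks[0]


def toy_epochset(data: np.ndarray, labels: list[str],
                 rate: float = 600.0, baseline: int = 0) -> na.EpochSet:
    """Wrap a trials x channels x points array as post-stimulus epochs."""
    return na.EpochSet(np.asarray(data, dtype=float), rate, labels,
                       baseline_samples=baseline)
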