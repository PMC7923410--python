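"""Shared fixtures: synthetic beat series at session scope (generation of a
24-h record costs ~0.1 s; spectral work on it is the expensive part)."""

import numpy as np
import pytest

from wearhrv.io_formats import BeatSeries
from wearhrv.synthetic import GeneratorProfile, generate_beats


@pytest.fixture(scope="session")
def healthy_record():
    """Default healthy 24-h record: corrupted series plus clean truth."""
    return generate_beats(GeneratorProfile(seed=1))


@pytest.fixture(scope="session")
def clean_series(healthy_record):
    return healthy_record.truth


@pytest.fixture(scope="session")
def short_clean_series():
    """A 4-h clean record for cheaper spectral/segmentation tests."""
    profile = GeneratorProfile(seed=4, duration_h=4.0, ectopic_rate=0.0, gap_rate_per_h=0.0)
    return generate_beats(profile).truth


def make_series(nn_ms, subject_id="test", t0_s=0.0):
    """Build a BeatSeries from NN intervals alone (cumulative timestamps)."""
    nn = np.asarray(nn_ms, dtype=float)
    t = t0_s + np.cumsum(nn) / 1000.0
    return BeatSeries(subject_id=subject_id, t=t, nn=nn)
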