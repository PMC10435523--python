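import numpy as np
import pytest

from piezobp import (
    CohortSpec,
    MorphologyParams,
    NoiseSpec,
    SubjectRecord,
    synth_beat,
    synth_dual_piezo,
)
from piezobp.preprocess import BeatSegment


@pytest.fixture(scope="session")
def subject() -> SubjectRecord:
    """A fixed reference subject: SBP 120 / DBP 80, HR 75, PWV 6 m/s."""
    return SubjectRecord(
        subject_id=0, age=30.0, sex="male", bmi=24.0,
        sbp=120.0, dbp=80.0, hr=75.0, pwv=6.0, seed=1234,
    )


@pytest.fixture(scope="session")
def clean_recording(subject):
    """10 s noise-free dual-channel recording at the 2000 Hz ADC rate."""
    return synth_dual_piezo(subject, duration=10.0, fs_per_channel=2000.0)


def beat_segment_from_subject(subj, fs=1000.0):
    """Normalized BeatSegment built from one synthetic beat, plus its truth."""
    beat = synth_beat(subj, fs=fs)
    x = beat.waveform.values
    seg = BeatSegment(
        values=(x - x.min()) / (x.max() - x.min()),
        fs=fs,
        start_index=0,
        raw_min=float(x.min()),
        raw_max=float(x.max()),
    )
    return seg, beat


@pytest.fixture(scope="session")
def clean_beat(subject):
    seg, beat = beat_segment_from_subject(subject)
    return seg, beat
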