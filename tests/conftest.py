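import numpy as np
import pytest

from physioattn import (
    ATTENTION,
    NONATTENTION,
    Modality,
    Recording,
    SegmentAnnotation,
    SignalWindow,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def ecg_recording(rng):
    """20 s two-condition ECG-like recording at 128 Hz."""
    rate = 128.0
    t = np.arange(int(20 * rate)) / rate
    samples = np.sin(2 * np.pi * 1.2 * t) + 0.1 * rng.normal(size=t.size)
    return Recording(
        subject_id="s0",
        modality=Modality.ECG,
        samples=samples,
        sampling_rate_hz=rate,
        annotations=[
            SegmentAnnotation(ATTENTION, 0.0, 10.0),
            SegmentAnnotation(NONATTENTION, 10.0, 20.0),
        ],
    )


def make_window(samples, rate=128.0, duration=10.0, label=ATTENTION):
    return SignalWindow(
        samples=samples,
        label=label,
        subject_id="s0",
        window_index=0,
        sampling_rate_hz=rate,
        duration_s=duration,
    )


@pytest.fixture
def small_window(rng):
    """Length-64 window (rate 6.4 Hz, 10 s) — cheap enough for O(N^2) oracles."""
    return make_window(rng.normal(size=64), rate=6.4, duration=10.0)
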