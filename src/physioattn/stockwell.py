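"""Discrete Stockwell transform (S-transform) of windowed signals.

The S-transform is a time-frequency decomposition using a frequency-scaled
Gaussian window that retains absolutely referenced phase.  For a length-``N``
series ``h[kT]`` with normalized spectrum

    H[n] = (1/N) Σ_k h[kT] exp(-2πi n k / N)

the discrete transform computed here is, for each retained voice ``n > 0``,

    S[j, n] = Σ_{m=0}^{N-1} H[(m+n) mod N] exp(-2π² m² / n²) exp(2πi m j / N)

with one output column per input sample.  The inner sum is an inverse DFT of
the Gaussian-windowed, shifted spectrum, so each voice costs one FFT; a naive
O(N²) evaluation of the same formula serves as a test oracle elsewhere.  The
``n = 0`` (DC) row is the window mean replicated across time.

Averaging a voice over time collapses the Gaussian sum to its ``m = 0`` term
and recovers ``H[n]`` exactly — the *time-marginal identity*, used as the
strongest correctness check.

Frequency stepping: with a 10 s window the native resolution is 0.1 Hz; a
1 Hz step keeps every 10th voice (no averaging of neighbouring voices), up to
the Nyquist frequency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import LABELS, ValidationError

__all__ = ["SignalWindow", "STMatrix", "window_signal", "dft", "stransform"]

#: Analysis window length in seconds (windows are non-overlapping).
DEFAULT_WINDOW_DURATION_S = 10.0

#: Frequency step between retained voices, in Hz.
DEFAULT_FREQ_STEP_HZ = 1.0


@dataclass
class SignalWindow:
    """One fixed-duration labelled analysis window of a segment."""

    samples: np.ndarray
    label: str
    subject_id: str
    window_index: int
    sampling_rate_hz: float
    duration_s: float = DEFAULT_WINDOW_DURATION_S

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.label not in LABELS:
            raise ValidationError(f"label must be one of {LABELS}, got {self.label!r}")
        expected = int(round(self.sampling_rate_hz * self.duration_s))
        if self.samples.size != expected:
            raise ValidationError(
                f"window holds {self.samples.size} samples; expected "
                f"round({self.sampling_rate_hz} Hz * {self.duration_s} s) = {expected}"
            )


@dataclass
class STMatrix:
    """Complex frequency × time matrix from the discrete S-transform."""

    values: np.ndarray
    freq_axis_hz: np.ndarray
    time_axis: np.ndarray
    source: SignalWindow | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.freq_axis_hz = np.asarray(self.freq_axis_hz, dtype=float)
        self.time_axis = np.asarray(self.time_axis)
        if self.values.shape != (self.freq_axis_hz.size, self.time_axis.size):
            raise ValidationError(
                f"matrix shape {self.values.shape} inconsistent with axes "
                f"({self.freq_axis_hz.size} freqs, {self.time_axis.size} times)"
            )
        if np.any(np.diff(self.freq_axis_hz) <= 0):
            raise ValidationError("freq_axis_hz must be strictly ascending")

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.values)


def window_signal(
    segment: np.ndarray,
    label: str,
    subject_id: str,
    sampling_rate_hz: float,
    duration_s: float = DEFAULT_WINDOW_DURATION_S,
    start_index: int = 0,
) -> list[SignalWindow]:
    """Partition a labelled segment into non-overlapping fixed-length windows.

    The trailing partial window is discarded.  A segment shorter than one
    window yields an empty list with a warning rather than an error, so
    short recordings degrade gracefully.
    """
    segment = np.asarray(segment, dtype=float)
    n = int(round(sampling_rate_hz * duration_s))
    if n < 1:
        raise ValidationError("window must contain at least 1 sample")
    k = segment.size // n
    if k == 0:
        warnings.warn(
            f"segment of {segment.size} samples shorter than one "
            f"{duration_s} s window ({n} samples); no windows produced",
            stacklevel=2,
        )
        return []
    return [
        SignalWindow(
            samples=segment[i * n : (i + 1) * n],
            label=label,
            subject_id=subject_id,
            window_index=start_index + i,
            sampling_rate_hz=sampling_rate_hz,
            duration_s=duration_s,
        )
        for i in range(k)
    ]


def dft(signal: np.ndarray) -> np.ndarray:
    """Normalized forward DFT: ``H[n] = (1/N) Σ_k h[k] exp(-2πi nk/N)``."""
    signal = np.asarray(signal)
    if signal.size == 0:
        raise ValidationError("cannot transform an empty signal")
    return np.fft.fft(signal) / signal.size


def stransform(
    window: SignalWindow,
    freq_step_hz: float = DEFAULT_FREQ_STEP_HZ,
    include_dc: bool = True,
) -> STMatrix:
    """Discrete S-transform of one window at stepped voice frequencies.

    Retains voices at ``freq_step_hz, 2*freq_step_hz, ... <= Nyquist`` (plus
    the DC row when ``include_dc``); one output column per input sample.
    """
    x = window.samples
    N = x.size
    T = 1.0 / window.sampling_rate_hz
    resolution = 1.0 / (N * T)
    if freq_step_hz < resolution - 1e-12:
        raise ValidationError(
            f"freq_step_hz {freq_step_hz} finer than the window's frequency "
            f"resolution {resolution:.6g} Hz"
        )
    nyquist = window.sampling_rate_hz / 2.0
    freqs = np.arange(1, int(np.floor(nyquist / freq_step_hz)) + 1) * freq_step_hz
    voices = np.rint(freqs * N * T).astype(int)
    if voices.size == 0:
        raise ValidationError("no voices at or below Nyquist for this step")

    H = np.fft.fft(x) / N
    m = np.arange(N, dtype=float)
    rows = np.empty((voices.size, N), dtype=complex)
    for i, n in enumerate(voices):
        gauss = np.exp(-2.0 * np.pi**2 * (m / n) ** 2)
        rows[i] = np.roll(H, -n) * gauss
    S = np.fft.ifft(rows, axis=1) * N

    if include_dc:
        dc = np.full((1, N), x.mean(), dtype=complex)
        S = np.vstack([dc, S])
        freqs = np.concatenate([[0.0], freqs])
    return STMatrix(
        values=S, freq_axis_hz=freqs, time_axis=np.arange(N), source=window
    )
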