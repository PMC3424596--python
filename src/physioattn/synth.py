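"""Synthetic multi-subject ECG / EEG cohorts with state-dependent structure.

The original recordings (21 ECG subjects at 128 Hz, 12 EEG subjects at
1000 Hz, ~20 min per stimulus condition) are not deposited, so this module
emulates them well enough that every pipeline stage has something real to do:

* **ECG** — a periodic PQRST-like train of Gaussian bumps whose beat-to-beat
  (RR) interval is drawn per beat from a state-dependent normal distribution,
  plus slow sinusoidal baseline wander and white measurement noise.  During
  the "attention" condition the mean RR shortens and the RR variability drops
  (sympathetic arousal); ``effect_size`` scales the log-contrast of both.
* **EEG** — a sum of five band-limited noise processes confined to the
  Delta…Gamma bands.  Attention raises Beta/Gamma power and lowers
  Theta/Alpha power, again on a log scale proportional to ``effect_size``;
  Delta is state-independent.

Subjects are exchangeable but not identical: each draws lognormal offsets for
its resting RR interval / band powers.  All randomness is counter-based —
every (seed, subject_index, modality) triple maps to its own independent
stream — so cohorts are reproducible element-wise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .eeg import EEG_BANDS, design_band_sos
from .io import ATTENTION, NONATTENTION, Modality, Recording, SegmentAnnotation, ValidationError

__all__ = [
    "SyntheticConfig",
    "generate_ecg_subject",
    "generate_eeg_subject",
    "generate_cohort",
]

# PQRST template: (offset from R peak [s], Gaussian width [s], amplitude).
# Amplitudes are in the R-peak-normalized unit system of the generator.
_PQRST = (
    (-0.20, 0.025, 0.12),   # P
    (-0.03, 0.010, -0.18),  # Q
    (0.00, 0.012, 1.00),    # R
    (0.03, 0.010, -0.25),   # S
    (0.27, 0.045, 0.35),    # T
)

# Resting-state cardiac parameters (seconds); attention multiplies the mean RR
# by exp(-_RR_MEAN_LOGSHIFT * effect_size) and the RR standard deviation by
# exp(-_RR_SD_LOGSHIFT * effect_size).
_RR_BASE_S = 0.85
_RR_SD_FRACTION = 0.06
_RR_MEAN_LOGSHIFT = 0.08
_RR_SD_LOGSHIFT = 0.40
_SUBJECT_RR_LOGSD = 0.05

# EEG band RMS amplitudes in the nonattention condition (arbitrary µV-like
# units, slow bands dominant as in resting frontal EEG); the sign says how
# attention moves the band (+1 raised, -1 lowered, 0 unchanged).
_EEG_BAND_AMPLITUDE = {
    "Delta": (2.0, 0),
    "Theta": (1.2, -1),
    "Alpha": (0.9, -1),
    "Beta": (0.55, +1),
    "Gamma": (0.35, +1),
}
_EEG_BAND_LOGSHIFT = 0.30
_SUBJECT_BAND_LOGSD = 0.10

_MODALITY_STREAM = {Modality.ECG: 0, Modality.EEG: 1}


@dataclass(frozen=True)
class SyntheticConfig:
    """Cohort-level generation settings.

    ``segment_duration_s`` is the length of *each* of the two stimulus
    conditions (default 1200 s, i.e. a ~20-minute montage per condition).
    ``effect_size`` scales the attention/nonattention contrast; 0 makes the
    two conditions draws from identical distributions.
    """

    n_subjects: int = 21
    segment_duration_s: float = 1200.0
    ecg_rate_hz: float = 128.0
    eeg_rate_hz: float = 1000.0
    seed: int = 0
    effect_size: float = 1.0
    noise_sd: float = 0.05
    baseline_wander_amplitude: float = 0.3

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValidationError("n_subjects must be >= 1")
        if not (self.segment_duration_s > 0):
            raise ValidationError("segment_duration_s must be positive")
        if not (self.ecg_rate_hz > 0 and self.eeg_rate_hz > 0):
            raise ValidationError("sampling rates must be positive")
        if self.effect_size < 0:
            raise ValidationError("effect_size must be >= 0")
        if self.noise_sd < 0 or self.baseline_wander_amplitude < 0:
            raise ValidationError("noise_sd and baseline_wander_amplitude must be >= 0")


def _subject_rng(config: SyntheticConfig, subject_index: int, modality: Modality) -> np.random.Generator:
    ss = np.random.SeedSequence(
        entropy=config.seed, spawn_key=(_MODALITY_STREAM[modality], subject_index)
    )
    return np.random.default_rng(ss)


def _ecg_segment(
    rng: np.random.Generator,
    n_samples: int,
    rate: float,
    rr_mean: float,
    rr_sd: float,
    wander_amp: float,
    noise_sd: float,
) -> np.ndarray:
    """One condition's worth of ECG: PQRST train + wander + white noise."""
    duration = n_samples / rate
    n_beats = int(duration / rr_mean * 1.5) + 8
    rr = rng.normal(rr_mean, rr_sd, size=n_beats)
    rr = np.clip(rr, 0.4 * rr_mean, 2.0 * rr_mean)
    beat_times = np.cumsum(rr) - rr[0] + 0.5 * rr_mean
    beat_times = beat_times[beat_times < duration + 0.5]

    x = np.zeros(n_samples)
    t = np.arange(n_samples) / rate
    for bt in beat_times:
        for off, width, amp in _PQRST:
            c = bt + off
            lo = max(0, int((c - 4 * width) * rate))
            hi = min(n_samples, int((c + 4 * width) * rate) + 1)
            if hi <= lo:
                continue
            x[lo:hi] += amp * np.exp(-0.5 * ((t[lo:hi] - c) / width) ** 2)

    # draws happen unconditionally so the stream (and hence the beat train)
    # is invariant to the wander / noise amplitude settings
    for f_lo, f_hi, w in ((0.12, 0.22, 1.0), (0.25, 0.40, 0.5)):
        f = rng.uniform(f_lo, f_hi)
        phase = rng.uniform(0, 2 * np.pi)
        if wander_amp > 0:
            x += wander_amp * w * np.sin(2 * np.pi * f * t + phase)
    if noise_sd > 0:
        x += rng.normal(0.0, noise_sd, size=n_samples)
    return x


def generate_ecg_subject(config: SyntheticConfig, subject_index: int) -> Recording:
    """Generate one subject's annotated two-condition ECG recording.

    The attention segment occupies ``[0, segment_duration_s)`` and the
    nonattention segment the second half; deterministic given
    ``(config.seed, subject_index)``.
    """
    rng = _subject_rng(config, subject_index, Modality.ECG)
    rate = config.ecg_rate_hz
    seg_n = int(round(config.segment_duration_s * rate))
    rr0 = _RR_BASE_S * np.exp(rng.normal(0.0, _SUBJECT_RR_LOGSD))
    sd0 = _RR_SD_FRACTION * rr0 * np.exp(rng.normal(0.0, 0.2))

    e = config.effect_size
    segments = []
    for label in (ATTENTION, NONATTENTION):
        if label == ATTENTION:
            rr_mean = rr0 * np.exp(-_RR_MEAN_LOGSHIFT * e)
            rr_sd = sd0 * np.exp(-_RR_SD_LOGSHIFT * e)
        else:
            rr_mean, rr_sd = rr0, sd0
        segments.append(
            _ecg_segment(
                rng, seg_n, rate, rr_mean, rr_sd,
                config.baseline_wander_amplitude, config.noise_sd,
            )
        )
    samples = np.concatenate(segments)
    dur = seg_n / rate
    annotations = [
        SegmentAnnotation(ATTENTION, 0.0, dur),
        SegmentAnnotation(NONATTENTION, dur, 2 * dur),
    ]
    return Recording(
        subject_id=f"ecg{subject_index:02d}",
        modality=Modality.ECG,
        samples=samples,
        sampling_rate_hz=rate,
        annotations=annotations,
    )


def _bandlimited_noise(
    rng: np.random.Generator, n_samples: int, sos: np.ndarray, rms: float
) -> np.ndarray:
    white = rng.normal(0.0, 1.0, size=n_samples)
    y = sps.sosfiltfilt(sos, white)
    scale = np.sqrt(np.mean(y**2))
    if scale == 0:
        return np.zeros(n_samples)
    return y * (rms / scale)


def generate_eeg_subject(config: SyntheticConfig, subject_index: int) -> Recording:
    """Generate one subject's annotated two-condition EEG recording."""
    rng = _subject_rng(config, subject_index, Modality.EEG)
    rate = config.eeg_rate_hz
    seg_n = int(round(config.segment_duration_s * rate))
    e = config.effect_size

    subject_gain = {
        band.name: np.exp(rng.normal(0.0, _SUBJECT_BAND_LOGSD)) for band in EEG_BANDS
    }
    sos_by_band = {b.name: design_band_sos(b, rate) for b in EEG_BANDS}

    segments = []
    for label in (ATTENTION, NONATTENTION):
        x = np.zeros(seg_n)
        for band in EEG_BANDS:
            base, direction = _EEG_BAND_AMPLITUDE[band.name]
            rms = base * subject_gain[band.name]
            if label == ATTENTION and direction:
                rms *= np.exp(direction * _EEG_BAND_LOGSHIFT * e)
            x += _bandlimited_noise(rng, seg_n, sos_by_band[band.name], rms)
        if config.noise_sd > 0:
            x += rng.normal(0.0, config.noise_sd, size=seg_n)
        segments.append(x)
    samples = np.concatenate(segments)
    dur = seg_n / rate
    annotations = [
        SegmentAnnotation(ATTENTION, 0.0, dur),
        SegmentAnnotation(NONATTENTION, dur, 2 * dur),
    ]
    return Recording(
        subject_id=f"eeg{subject_index:02d}",
        modality=Modality.EEG,
        samples=samples,
        sampling_rate_hz=rate,
        annotations=annotations,
    )


def generate_cohort(config: SyntheticConfig, modality: Modality = Modality.ECG) -> list[Recording]:
    """Generate ``config.n_subjects`` recordings of one modality.

    Subject ids are distinct; regeneration with the same config is
    bit-identical because each subject owns a counter-derived stream.
    """
    modality = Modality(modality)
    gen = generate_ecg_subject if modality is Modality.ECG else generate_eeg_subject
    return [gen(config, i) for i in range(config.n_subjects)]
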