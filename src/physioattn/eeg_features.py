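"""Band-wise wavelet decomposition and the 210-feature EEG vector.

Each band component of a labelled segment is cut into non-overlapping 10 s
windows (10000 samples at 1000 Hz).  Every window is decomposed with a
5-level Mallat cascade using a band-specific mother wavelet — ``bior3.9``
for Gamma, ``db4`` for Delta/Theta/Alpha, ``coif3`` for Beta — retaining the
detail coefficients D1..D5 and the level-5 approximation A5 (six coefficient
vectors).  Seven statistics per vector × 6 vectors × 5 bands = 210 features
per window, with stable names ``"band.coef.stat"``.

The seven per-coefficient statistics, in fixed order:

1. ``rms`` — sqrt((1/n) Σ x²).  The source formula labels this "standard
   deviation" but contains no mean-centering; it is implemented as printed
   (root-mean-square).  ``centered=True`` switches to the conventional
   population standard deviation.
2. ``entropy`` — Shannon entropy in bits of the normalized histogram
   (Rice-style bin count ``2·ceil(n^(1/3))`` by default; empty bins skipped).
3. ``log2_var`` — log2 of the population variance (NaN if zero).
4. ``fourier_mean`` — mean of the DFT magnitudes.
5. ``hist_var`` — population variance of the normalized histogram vector
   (the empirical probability distribution).
6. ``autocorr_sum`` — sum of the autocorrelation sequence.
7. ``autocov_mean`` — mean of the autocovariance sequence.

Autocovariance / autocorrelation / variance conventions are shared with the
ECG feature family (see ``_stats``).  DWT boundary handling is half-sample
symmetric extension.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pywt

from ._stats import (
    autocorrelation_sequence,
    autocovariance_sequence,
    log2_variance,
    population_variance,
)
from .eeg import BAND_NAMES
from .io import LABELS, ValidationError

__all__ = [
    "WaveletPlan",
    "WaveletCoefficients",
    "DEFAULT_WAVELET_PLAN",
    "COEF_NAMES",
    "COEF_STAT_NAMES",
    "EEG_FEATURE_NAMES",
    "dwt_decompose",
    "coefficient_features",
    "extract_eeg_features",
]

#: Coefficient vectors retained from the 5-level cascade, in fixed order.
COEF_NAMES = ("D1", "D2", "D3", "D4", "D5", "A5")

#: Per-coefficient statistics, in fixed order.
COEF_STAT_NAMES = (
    "rms",
    "entropy",
    "log2_var",
    "fourier_mean",
    "hist_var",
    "autocorr_sum",
    "autocov_mean",
)

_DWT_MODE = "symmetric"


@dataclass(frozen=True)
class WaveletPlan:
    """Mother-wavelet assignment per band plus the decomposition depth."""

    wavelets: Mapping[str, str] = field(
        default_factory=lambda: {
            "Delta": "db4",
            "Theta": "db4",
            "Alpha": "db4",
            "Beta": "coif3",
            "Gamma": "bior3.9",
        }
    )
    levels: int = 5

    def __post_init__(self) -> None:
        missing = [b for b in BAND_NAMES if b not in self.wavelets]
        if missing:
            raise ValidationError(f"wavelet plan missing bands: {missing}")
        if self.levels < 1:
            raise ValidationError("levels must be >= 1")
        for band, name in self.wavelets.items():
            if name not in pywt.wavelist(kind="discrete"):
                raise ValidationError(f"unknown mother wavelet {name!r} for {band}")


DEFAULT_WAVELET_PLAN = WaveletPlan()

#: Full ordered 210-name registry (Delta..Gamma × D1..D5,A5 × 7 stats).
EEG_FEATURE_NAMES = tuple(
    f"{band}.{coef}.{stat}"
    for band in BAND_NAMES
    for coef in COEF_NAMES
    for stat in COEF_STAT_NAMES
)


@dataclass
class WaveletCoefficients:
    """D1..D5 detail vectors plus the level-5 approximation A5."""

    details: list[np.ndarray]
    approximation: np.ndarray
    wavelet: str
    band: str | None = None

    def by_name(self) -> dict[str, np.ndarray]:
        out = {f"D{i + 1}": d for i, d in enumerate(self.details)}
        out[f"A{len(self.details)}"] = self.approximation
        return out


def dwt_decompose(
    window_samples: np.ndarray, wavelet: str, levels: int = 5, band: str | None = None
) -> WaveletCoefficients:
    """Run the Mallat analysis cascade on one window.

    Symmetric (half-sample) boundary extension throughout; coefficient
    lengths follow the halving-plus-filter-overhang rule of the cascade.
    """
    x = np.asarray(window_samples, dtype=float)
    if x.size < 2**levels:
        raise ValidationError(
            f"window of {x.size} samples too short for {levels} levels"
        )
    if wavelet not in pywt.wavelist(kind="discrete"):
        raise ValidationError(f"unknown mother wavelet {wavelet!r}")
    coeffs = pywt.wavedec(x, wavelet, mode=_DWT_MODE, level=levels)
    approx = coeffs[0]
    details = list(reversed(coeffs[1:]))  # D1 (finest) .. D5 (coarsest)
    return WaveletCoefficients(
        details=details, approximation=approx, wavelet=wavelet, band=band
    )


def _histogram_p(x: np.ndarray, bins: int | None) -> np.ndarray:
    if bins is None:
        bins = 2 * int(np.ceil(x.size ** (1.0 / 3.0)))
    counts, _ = np.histogram(x, bins=bins)
    return counts / x.size


def shannon_entropy_bits(x: np.ndarray, bins: int | None = None) -> float:
    """Histogram entropy −Σ p log2 p, skipping empty bins."""
    p = _histogram_p(np.asarray(x, dtype=float), bins)
    p = p[p > 0]
    return float(-np.sum(p * np.log2(p)))


def coefficient_features(
    coeffs: np.ndarray, bins: int | None = None, centered: bool = False
) -> dict[str, float]:
    """The seven named statistics of one coefficient vector."""
    x = np.asarray(coeffs, dtype=float)
    if x.size < 2:
        raise ValidationError("coefficient vector must have >= 2 values")
    if centered:
        rms = float(np.sqrt(population_variance(x)))
    else:
        rms = float(np.sqrt(np.mean(x**2)))
    p = _histogram_p(x, bins)
    pn = p[p > 0]
    acov = autocovariance_sequence(x)
    acorr = autocorrelation_sequence(x)
    return {
        "rms": rms,
        "entropy": float(-np.sum(pn * np.log2(pn))),
        "log2_var": log2_variance(x),
        "fourier_mean": float(np.mean(np.abs(np.fft.fft(x)))),
        "hist_var": population_variance(p),
        "autocorr_sum": float(acorr.sum()),
        "autocov_mean": float(acov.mean()),
    }


def extract_eeg_features(
    band_segments: Mapping[str, np.ndarray],
    label: str,
    subject_id: str,
    sampling_rate_hz: float,
    plan: WaveletPlan = DEFAULT_WAVELET_PLAN,
    window_duration_s: float = 10.0,
    start_index: int = 0,
    bins: int | None = None,
    centered_rms: bool = False,
) -> list[dict]:
    """Per-window 210-feature rows for one labelled segment.

    ``band_segments`` maps each of the five band names to that band's
    time-aligned component of the segment.  Windows are non-overlapping,
    ``round(rate * duration)`` samples each; the trailing partial window is
    dropped.  Returns feature-table rows (dicts with ``subject_id``,
    ``window_index``, ``label`` and the 210 named features).
    """
    if label not in LABELS:
        raise ValidationError(f"label must be one of {LABELS}, got {label!r}")
    missing = [b for b in BAND_NAMES if b not in band_segments]
    if missing:
        raise ValidationError(f"band segments missing: {missing}")
    lengths = {b: len(band_segments[b]) for b in BAND_NAMES}
    if len(set(lengths.values())) != 1:
        raise ValidationError(f"band segments not aligned: lengths {lengths}")
    n = int(round(sampling_rate_hz * window_duration_s))
    n_windows = lengths["Delta"] // n

    rows: list[dict] = []
    for w in range(n_windows):
        row: dict = {
            "subject_id": subject_id,
            "window_index": start_index + w,
            "label": label,
        }
        for band in BAND_NAMES:
            chunk = np.asarray(band_segments[band][w * n : (w + 1) * n], dtype=float)
            decomp = dwt_decompose(chunk, plan.wavelets[band], levels=plan.levels, band=band)
            for coef_name, vec in decomp.by_name().items():
                stats = coefficient_features(vec, bins=bins, centered=centered_rms)
                for stat_name in COEF_STAT_NAMES:
                    row[f"{band}.{coef_name}.{stat_name}"] = stats[stat_name]
        rows.append(row)
    return rows
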