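"""Reduce each window's S-transform matrix to 27 named ECG features.

All statistics operate on the magnitude matrix ``|ST|`` (products, ranges and
maxima are ill-defined on complex values).  Extraction runs in two steps:

1. **Frequency reduction** — per time column, compute mean, sum, product,
   population standard deviation and range across the frequency rows, giving
   five time series ("frequency-reduced series").
2. **Time summarization** — for each of the five series compute its mean,
   sum, mean of the autocovariance sequence, sum of the autocorrelation
   sequence, and log2 of the (population) variance.

That yields 5 × 5 = 25 features; two matrix-level features complete the set:
the mean over time of the per-column frequency maximum, and the mean absolute
deviation of all matrix entries about the grand mean.  Total: 27 per window,
in a fixed order with deterministic names like ``"std_f.autocorr_sum"``.

The per-column product multiplies ~65 magnitudes typically far below 1, which
underflows a naive product; it is computed as ``exp(Σ log)`` with each factor
clamped below at the smallest positive normal float.  The DC (0 Hz) row
participates in all reductions by default.
"""

from __future__ import annotations

import numpy as np

from ._stats import (
    autocorrelation_sequence,
    autocovariance_sequence,
    log2_variance,
)
from .io import ValidationError
from .stockwell import STMatrix

__all__ = [
    "FREQ_SERIES_NAMES",
    "TIME_STAT_NAMES",
    "ECG_FEATURE_NAMES",
    "reduce_over_frequency",
    "summarize_over_time",
    "matrix_level_features",
    "extract_ecg_features",
]

#: Frequency-reduction series, in fixed order.
FREQ_SERIES_NAMES = ("mean_f", "sum_f", "product_f", "std_f", "range_f")

#: Time-domain summary statistics, in fixed order.
TIME_STAT_NAMES = ("mean", "sum", "autocov_mean", "autocorr_sum", "log2_var")

#: Matrix-level features appended after the 25 series statistics.
MATRIX_FEATURE_NAMES = ("max_freq_mean", "mean_abs_dev")

#: The full, ordered 27-name registry.
ECG_FEATURE_NAMES = tuple(
    f"{series}.{stat}" for series in FREQ_SERIES_NAMES for stat in TIME_STAT_NAMES
) + MATRIX_FEATURE_NAMES

_TINY = np.finfo(float).tiny


def reduce_over_frequency(
    st: STMatrix, include_dc: bool = True
) -> dict[str, np.ndarray]:
    """Collapse ``|ST|`` across frequency rows, keeping time discrete.

    Returns the five frequency-reduced series keyed and ordered per
    :data:`FREQ_SERIES_NAMES`.  ``include_dc=False`` drops the 0 Hz row
    before reducing.
    """
    mag = st.magnitude
    if not include_dc and st.freq_axis_hz[0] == 0.0:
        mag = mag[1:]
    if mag.size == 0:
        raise ValidationError("empty S-transform matrix")
    log_prod = np.sum(np.log(np.maximum(mag, _TINY)), axis=0)
    return {
        "mean_f": mag.mean(axis=0),
        "sum_f": mag.sum(axis=0),
        "product_f": np.exp(log_prod),
        "std_f": mag.std(axis=0),  # population
        "range_f": mag.max(axis=0) - mag.min(axis=0),
    }


def summarize_over_time(series: np.ndarray) -> dict[str, float]:
    """The five time-domain statistics of one frequency-reduced series.

    For a zero-variance series the log-variance and autocorrelation-sum
    entries are NaN (serialized as ``NA``), never silent zeros.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 2:
        raise ValidationError("series must have at least 2 time points")
    acov = autocovariance_sequence(x)
    acorr = autocorrelation_sequence(x)
    return {
        "mean": float(x.mean()),
        "sum": float(x.sum()),
        "autocov_mean": float(acov.mean()),
        "autocorr_sum": float(acorr.sum()),  # NaN propagates for constant series
        "log2_var": log2_variance(x),
    }


def matrix_level_features(st: STMatrix, include_dc: bool = True) -> dict[str, float]:
    """The two whole-matrix features: mean column maximum and MAD."""
    mag = st.magnitude
    if not include_dc and st.freq_axis_hz[0] == 0.0:
        mag = mag[1:]
    if mag.size == 0:
        raise ValidationError("empty S-transform matrix")
    return {
        "max_freq_mean": float(mag.max(axis=0).mean()),
        "mean_abs_dev": float(np.mean(np.abs(mag - mag.mean()))),
    }


def extract_ecg_features(st: STMatrix, include_dc: bool = True) -> dict[str, float]:
    """The ordered 27-feature vector for one window's S-transform."""
    out: dict[str, float] = {}
    reduced = reduce_over_frequency(st, include_dc=include_dc)
    for series_name in FREQ_SERIES_NAMES:
        stats = summarize_over_time(reduced[series_name])
        for stat_name in TIME_STAT_NAMES:
            out[f"{series_name}.{stat_name}"] = stats[stat_name]
    out.update(matrix_level_features(st, include_dc=include_dc))
    assert tuple(out) == ECG_FEATURE_NAMES
    return out
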