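"""Shared statistic conventions used by both feature families.

Fixed conventions (applied identically to ECG and EEG features):

* variance is **population** variance (divide by n);
* the autocovariance sequence is the biased estimate over all non-negative
  lags, ``c(l) = (1/n) Σ_{t} (x_t - x̄)(x_{t+l} - x̄)`` for ``l = 0..n-1``;
* the autocorrelation sequence is ``r(l) = c(l) / c(0)``, undefined (NaN)
  for a constant series;
* undefined values (log of zero variance, 0/0 autocorrelation) are NaN,
  which the I/O layer serializes as the ``NA`` sentinel.

The autocovariance is computed via the Wiener-Khinchin route (FFT of the
zero-padded centred series); tests compare it against a literal O(n²)
double-loop definition.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "population_variance",
    "autocovariance_sequence",
    "autocorrelation_sequence",
    "log2_variance",
]


def population_variance(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    return float(np.mean((x - x.mean()) ** 2))


def autocovariance_sequence(x: np.ndarray) -> np.ndarray:
    """Biased autocovariance at lags 0..n-1."""
    x = np.asarray(x, dtype=float)
    n = x.size
    xc = x - x.mean()
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    spec = np.fft.rfft(xc, nfft)
    acov = np.fft.irfft(spec * np.conj(spec), nfft)[:n] / n
    return acov


def autocorrelation_sequence(x: np.ndarray) -> np.ndarray:
    """Autocovariance normalized by lag-0; all-NaN for a constant series."""
    acov = autocovariance_sequence(x)
    c0 = acov[0]
    if c0 <= 0:
        return np.full_like(acov, np.nan)
    return acov / c0


def log2_variance(x: np.ndarray) -> float:
    """log2 of the population variance; NaN for a zero-variance series."""
    var = population_variance(x)
    if var <= 0:
        return float("nan")
    return float(np.log2(var))
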