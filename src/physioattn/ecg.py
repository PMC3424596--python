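"""ECG preprocessing: polynomial smoothing, baseline-wander removal, splitting.

The cleaning chain runs in a fixed order: Savitzky-Golay least-squares
smoothing, then per-window regression-line baseline removal, then splitting
into labelled segments by annotation timestamps.

Baseline removal partitions the signal into consecutive non-overlapping
windows of ``round(sampling_rate_hz)`` samples (i.e. one second each) and
subtracts from each window the ordinary-least-squares line

    m = (n Σxy − Σx Σy) / (n Σx² − (Σx)²),    b = (Σy − m Σx) / n

fitted to that window's samples.  Because the fit includes an intercept, the
residual of each window sums to zero exactly; a second application is a
no-op up to rounding.  Per-window subtraction can leave step discontinuities
at window joins; these are accepted as-is.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .io import Recording, ValidationError

__all__ = [
    "BaselineFit",
    "sgolay_smooth",
    "fit_baseline_window",
    "remove_baseline",
    "split_segments",
]

#: Default Savitzky-Golay frame / order: a 15-sample cubic frame at 128 Hz
#: smooths high-frequency noise while preserving QRS morphology.
DEFAULT_SG_WINDOW = 15
DEFAULT_SG_ORDER = 3


@dataclass(frozen=True)
class BaselineFit:
    """OLS line (slope ``m``, intercept ``b``) over one baseline window.

    ``b`` is referenced to the global sample-index axis: the fitted value at
    absolute index ``x`` is ``m*x + b``.
    """

    m: float
    b: float
    window_start: int
    window_length: int

    def __post_init__(self) -> None:
        if self.window_length < 2:
            raise ValidationError("baseline window needs >= 2 samples")

    def line(self) -> np.ndarray:
        x = self.window_start + np.arange(self.window_length)
        return self.m * x + self.b


def sgolay_smooth(
    signal: np.ndarray,
    window_length: int = DEFAULT_SG_WINDOW,
    poly_order: int = DEFAULT_SG_ORDER,
) -> np.ndarray:
    """Savitzky-Golay smoothing: centred least-squares polynomial frames.

    Reproduces any polynomial of degree ``<= poly_order`` exactly (edges
    included, via polynomial extrapolation of the boundary frames).
    """
    signal = np.asarray(signal, dtype=float)
    if window_length % 2 == 0:
        raise ValidationError(f"window_length must be odd, got {window_length}")
    if poly_order >= window_length:
        raise ValidationError(
            f"poly_order ({poly_order}) must be < window_length ({window_length})"
        )
    if window_length > signal.size:
        raise ValidationError(
            f"window_length ({window_length}) exceeds signal length ({signal.size})"
        )
    return savgol_filter(signal, window_length, poly_order, mode="interp")


def fit_baseline_window(points: np.ndarray, x_start: int = 0) -> BaselineFit:
    """Fit the best line to one window of consecutive samples.

    Abscissae are the absolute sample indices ``x_start .. x_start+n-1``;
    ordinates are the sample values.
    """
    y = np.asarray(points, dtype=float)
    n = y.size
    if n < 2:
        raise ValidationError("need at least 2 points to fit a line")
    x = x_start + np.arange(n, dtype=float)
    sx, sy = x.sum(), y.sum()
    sxy = float(x @ y)
    sxx = float(x @ x)
    denom = n * sxx - sx * sx
    m = (n * sxy - sx * sy) / denom
    b = (sy - m * sx) / n
    return BaselineFit(m=m, b=b, window_start=int(x_start), window_length=n)


def remove_baseline(signal: np.ndarray, sampling_rate_hz: float) -> np.ndarray:
    """Subtract a per-second OLS regression line from the signal.

    The window size equals ``round(sampling_rate_hz)`` samples.  A trailing
    partial window of >= 2 samples gets its own fit; a single trailing sample
    is passed through unchanged.
    """
    y = np.asarray(signal, dtype=float)
    if y.size == 0:
        raise ValidationError("cannot remove baseline from an empty signal")
    w = int(round(sampling_rate_hz))
    if w < 2:
        raise ValidationError(f"sampling rate {sampling_rate_hz} gives window < 2 samples")
    if y.size < w:
        raise ValidationError(
            f"signal length {y.size} shorter than one baseline window ({w})"
        )
    out = y.copy()
    n_full = y.size // w
    if n_full:
        block = y[: n_full * w].reshape(n_full, w)
        x = np.arange(w, dtype=float)
        xc = x - x.mean()
        denom = float(xc @ xc)
        slope = (block @ xc) / denom
        resid = block - block.mean(axis=1, keepdims=True) - slope[:, None] * xc[None, :]
        out[: n_full * w] = resid.reshape(-1)
    tail = y.size - n_full * w
    if tail >= 2:
        fit = fit_baseline_window(y[n_full * w :], x_start=n_full * w)
        out[n_full * w :] = y[n_full * w :] - fit.line()
    return out


def split_segments(recording: Recording) -> list[tuple[str, np.ndarray]]:
    """Cut out each annotated interval as a labelled sample sequence.

    Sample ranges are ``[floor(start_s*rate), floor(end_s*rate))``, matching
    the half-open time convention.
    """
    if not recording.annotations:
        raise ValidationError("recording has no annotations to split on")
    rate = recording.sampling_rate_hz
    n = recording.samples.size
    out: list[tuple[str, np.ndarray]] = []
    for ann in recording.annotations:
        i0 = int(np.floor(ann.start_s * rate))
        i1 = int(np.floor(ann.end_s * rate))
        if i0 >= n or i1 > n:
            raise ValidationError(
                f"annotation [{ann.start_s}, {ann.end_s}) s lies outside the "
                f"recording ({n} samples at {rate} Hz)"
            )
        out.append((ann.label, recording.samples[i0:i1].copy()))
    return out
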