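import math

import numpy as np
import pytest
import pywt

from physioattn import (
    ATTENTION,
    EEG_FEATURE_NAMES,
    ValidationError,
    WaveletPlan,
    coefficient_features,
    dwt_decompose,
    extract_eeg_features,
)
from physioattn.eeg import BAND_NAMES

from test_ecg_features import acorr_loop, acov_loop, var_pop_loop

PLAN_WAVELETS = ("db4", "coif3", "bior3.9")


# ---------------------------------------------------------------------------
# Independent literal implementations of the seven coefficient statistics.
# ---------------------------------------------------------------------------

def rms_loop(x):
    return math.sqrt(sum(v * v for v in x) / len(x))


def hist_p(x, k):
    lo, hi = min(x), max(x)
    edges = [lo + (hi - lo) * i / k for i in range(k)] + [hi]
    counts = [0] * k
    for v in x:
        for b in range(k):
            # numpy convention: half-open bins, last bin closed
            if edges[b] <= v < edges[b + 1] or (b == k - 1 and v == edges[k]):
                counts[b] += 1
                break
    return [c / len(x) for c in counts]


def entropy_loop(x, k):
    return -sum(p * math.log2(p) for p in hist_p(x, k) if p > 0)


def dft_mag_mean_loop(x):
    n = len(x)
    total = 0.0
    for f in range(n):
        acc = sum(x[t] * np.exp(-2j * np.pi * f * t / n) for t in range(n))
        total += abs(acc)
    return total / n


class TestDwtDecompose:
    def test_constant_signal_has_vanishing_details(self):
        coeffs = dwt_decompose(np.full(512, 2.0), "db4", levels=5)
        for d in coeffs.details:
            np.testing.assert_allclose(d, 0.0, atol=1e-10)
        assert np.all(np.abs(coeffs.approximation) > 1.0)

    def test_linear_ramp_interior_details_vanish(self):
        coeffs = dwt_decompose(np.linspace(0, 1, 1024), "db4", levels=5)
        for d in coeffs.details:
            interior = d[10:-10]  # symmetric extension perturbs boundary coeffs
            np.testing.assert_allclose(interior, 0.0, atol=1e-10)

    @pytest.mark.parametrize("wavelet", PLAN_WAVELETS)
    def test_perfect_reconstruction_length_10000(self, rng, wavelet):
        x = rng.normal(size=10000)
        c = dwt_decompose(x, wavelet, levels=5)
        rec = pywt.waverec(
            [c.approximation] + list(reversed(c.details)), wavelet, mode="symmetric"
        )
        np.testing.assert_allclose(rec[: x.size], x, atol=1e-8)

    @pytest.mark.parametrize("wavelet", ["db4", "coif3"])
    def test_energy_partition_for_orthogonal_wavelets(self, rng, wavelet):
        # not asserted for bior3.9: biorthogonal bases do not preserve energy
        x = rng.normal(size=4096)
        c = dwt_decompose(x, wavelet, levels=5)
        coef_energy = sum(float(v @ v) for v in c.details) + float(
            c.approximation @ c.approximation
        )
        # symmetric extension adds boundary coefficients, so allow slack
        assert coef_energy == pytest.approx(float(x @ x), rel=0.05)

    def test_six_coefficient_vectors_with_cascade_lengths(self, rng):
        c = dwt_decompose(rng.normal(size=10000), "db4", levels=5)
        assert len(c.details) == 5
        lengths = [d.size for d in c.details]
        assert lengths == sorted(lengths, reverse=True)  # D1 finest, D5 coarsest
        assert c.approximation.size == c.details[-1].size

    def test_unknown_wavelet_and_short_window_rejected(self):
        with pytest.raises(ValidationError, match="unknown"):
            dwt_decompose(np.zeros(256), "notawavelet", 5)
        with pytest.raises(ValidationError, match="short"):
            dwt_decompose(np.zeros(16), "db4", 5)


class TestCoefficientFeatures:
    def test_rms_as_printed_hand_arithmetic(self):
        feats = coefficient_features(np.array([3.0, 4.0]))
        assert feats["rms"] == pytest.approx(math.sqrt(12.5))

    def test_centered_flag_gives_conventional_std(self):
        x = np.array([3.0, 4.0])
        feats = coefficient_features(x, centered=True)
        assert feats["rms"] == pytest.approx(0.5)  # population std of [3, 4]

    def test_uniform_16_bin_histogram_has_4_bits_entropy(self):
        x = np.repeat(np.arange(16.0), 4)
        feats = coefficient_features(x, bins=16)
        assert feats["entropy"] == pytest.approx(4.0)

    def test_constant_vector_yields_na_sentinels(self):
        feats = coefficient_features(np.full(32, 1.5))
        assert math.isnan(feats["log2_var"])
        assert math.isnan(feats["autocorr_sum"])
        assert feats["rms"] == pytest.approx(1.5)

    @pytest.mark.parametrize("n", [16, 64])
    def test_random_vector_against_literal_oracles(self, rng, n):
        x = rng.normal(size=n)
        k = 2 * math.ceil(n ** (1 / 3))
        feats = coefficient_features(x)
        assert feats["rms"] == pytest.approx(rms_loop(x))
        assert feats["entropy"] == pytest.approx(entropy_loop(x, k))
        assert feats["log2_var"] == pytest.approx(math.log2(var_pop_loop(x)))
        assert feats["fourier_mean"] == pytest.approx(dft_mag_mean_loop(x), rel=1e-9)
        assert feats["hist_var"] == pytest.approx(var_pop_loop(hist_p(x, k)))
        assert feats["autocorr_sum"] == pytest.approx(acorr_loop(x).sum(), rel=1e-9)
        assert feats["autocov_mean"] == pytest.approx(acov_loop(x).mean(), rel=1e-9)


class TestExtractEegFeatures:
    def make_segments(self, rng, n):
        return {name: rng.normal(size=n) for name in BAND_NAMES}

    def test_each_row_has_210_named_features(self, rng):
        rows = extract_eeg_features(
            self.make_segments(rng, 10000), ATTENTION, "e0", 1000.0
        )
        assert len(rows) == 1
        feats = {k: v for k, v in rows[0].items()
                 if k not in ("subject_id", "window_index", "label")}
        assert tuple(feats) == EEG_FEATURE_NAMES
        assert len(feats) == 210

    def test_thirty_seconds_gives_three_rows(self, rng):
        rows = extract_eeg_features(
            self.make_segments(rng, 30000), ATTENTION, "e0", 1000.0
        )
        assert [r["window_index"] for r in rows] == [0, 1, 2]

    def test_per_band_block_is_42_wide(self, rng):
        rows = extract_eeg_features(
            self.make_segments(rng, 10000), ATTENTION, "e0", 1000.0
        )
        for band in BAND_NAMES:
            block = [k for k in rows[0] if k.startswith(f"{band}.")]
            assert len(block) == 42

    def test_identical_windows_give_identical_rows(self, rng):
        segs = self.make_segments(rng, 10000)
        r1 = extract_eeg_features(segs, ATTENTION, "e0", 1000.0)
        r2 = extract_eeg_features(segs, ATTENTION, "e0", 1000.0)
        assert r1 == r2

    def test_missing_band_rejected(self, rng):
        segs = self.make_segments(rng, 10000)
        del segs["Beta"]
        with pytest.raises(ValidationError, match="Beta"):
            extract_eeg_features(segs, ATTENTION, "e0", 1000.0)

    def test_misaligned_bands_rejected(self, rng):
        segs = self.make_segments(rng, 10000)
        segs["Gamma"] = segs["Gamma"][:-1]
        with pytest.raises(ValidationError, match="aligned"):
            extract_eeg_features(segs, ATTENTION, "e0", 1000.0)

    def test_wavelet_plan_fixed_table(self):
        plan = WaveletPlan()
        assert plan.wavelets["Gamma"] == "bior3.9"
        assert plan.wavelets["Beta"] == "coif3"
        assert all(plan.wavelets[b] == "db4" for b in ("Delta", "Theta", "Alpha"))
        assert plan.levels == 5
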