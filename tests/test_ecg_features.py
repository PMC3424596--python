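import math

import numpy as np
import pytest

from physioattn import (
    ECG_FEATURE_NAMES,
    ValidationError,
    extract_ecg_features,
    matrix_level_features,
    reduce_over_frequency,
    stransform,
    summarize_over_time,
)
from physioattn.stockwell import STMatrix

from conftest import make_window

# ---------------------------------------------------------------------------
# Literal-definition oracles, written independently of the implementation.
# ---------------------------------------------------------------------------

def acov_loop(x):
    """Biased autocovariance c(l) = (1/n) sum_t (x_t - xbar)(x_{t+l} - xbar)."""
    x = np.asarray(x, float)
    n = x.size
    xbar = sum(x) / n
    return np.array(
        [sum((x[t] - xbar) * (x[t + l] - xbar) for t in range(n - l)) / n
         for l in range(n)]
    )


def acorr_loop(x):
    c = acov_loop(x)
    return c / c[0]


def var_pop_loop(x):
    x = np.asarray(x, float)
    mu = sum(x) / x.size
    return sum((v - mu) ** 2 for v in x) / x.size


def st_from_matrix(mag):
    """Wrap a magnitude matrix as an STMatrix (values already real >= 0)."""
    mag = np.asarray(mag, dtype=float)
    f, n = mag.shape
    return STMatrix(
        values=mag.astype(complex),
        freq_axis_hz=np.arange(f, dtype=float),
        time_axis=np.arange(n),
    )


class TestReduceOverFrequency:
    def test_all_ones_matrix(self):
        red = reduce_over_frequency(st_from_matrix(np.ones((4, 6))))
        np.testing.assert_allclose(red["mean_f"], 1.0)
        np.testing.assert_allclose(red["sum_f"], 4.0)
        np.testing.assert_allclose(red["product_f"], 1.0)
        np.testing.assert_allclose(red["std_f"], 0.0, atol=1e-15)
        np.testing.assert_allclose(red["range_f"], 0.0)

    def test_single_row_matrix_degenerates(self):
        row = np.array([[1.0, 2.0, 3.0]])
        red = reduce_over_frequency(st_from_matrix(row))
        np.testing.assert_allclose(red["mean_f"], row[0])
        np.testing.assert_allclose(red["sum_f"], row[0])
        np.testing.assert_allclose(red["product_f"], row[0])
        np.testing.assert_allclose(red["std_f"], 0.0, atol=1e-15)
        np.testing.assert_allclose(red["range_f"], 0.0)

    def test_two_by_two_hand_arithmetic(self):
        red = reduce_over_frequency(st_from_matrix([[1.0, 2.0], [3.0, 4.0]]))
        np.testing.assert_allclose(red["mean_f"], [2.0, 3.0])
        np.testing.assert_allclose(red["sum_f"], [4.0, 6.0])
        np.testing.assert_allclose(red["product_f"], [3.0, 8.0])
        np.testing.assert_allclose(red["range_f"], [2.0, 2.0])

    def test_product_log_route_matches_direct_product(self, rng):
        mag = rng.uniform(0.1, 2.0, size=(8, 16))
        red = reduce_over_frequency(st_from_matrix(mag))
        np.testing.assert_allclose(red["product_f"], mag.prod(axis=0), rtol=1e-10)

    def test_population_std_convention(self, rng):
        mag = rng.uniform(0.0, 1.0, size=(7, 5))
        red = reduce_over_frequency(st_from_matrix(mag))
        np.testing.assert_allclose(
            red["std_f"], [math.sqrt(var_pop_loop(mag[:, j])) for j in range(5)]
        )


class TestSummarizeOverTime:
    def test_one_two_three_hand_arithmetic(self):
        stats = summarize_over_time(np.array([1.0, 2.0, 3.0]))
        assert stats["mean"] == pytest.approx(2.0)
        assert stats["sum"] == pytest.approx(6.0)
        assert stats["log2_var"] == pytest.approx(math.log2(2.0 / 3.0))

    def test_constant_series_yields_na_sentinels(self):
        stats = summarize_over_time(np.full(10, 4.0))
        assert stats["mean"] == pytest.approx(4.0)
        assert stats["sum"] == pytest.approx(40.0)
        assert stats["autocov_mean"] == pytest.approx(0.0, abs=1e-12)
        assert math.isnan(stats["autocorr_sum"])
        assert math.isnan(stats["log2_var"])

    def test_alternating_series_against_double_loop_oracle(self):
        x = np.array([1.0, -1.0, 1.0, -1.0])
        stats = summarize_over_time(x)
        assert stats["autocov_mean"] == pytest.approx(acov_loop(x).mean())
        assert stats["autocorr_sum"] == pytest.approx(acorr_loop(x).sum())

    @pytest.mark.parametrize("n", [8, 33, 64])
    def test_random_series_against_literal_oracles(self, rng, n):
        x = rng.normal(size=n)
        stats = summarize_over_time(x)
        assert stats["mean"] == pytest.approx(sum(x) / n)
        assert stats["sum"] == pytest.approx(sum(x))
        assert stats["autocov_mean"] == pytest.approx(acov_loop(x).mean(), rel=1e-9)
        assert stats["autocorr_sum"] == pytest.approx(acorr_loop(x).sum(), rel=1e-9)
        assert stats["log2_var"] == pytest.approx(math.log2(var_pop_loop(x)), rel=1e-9)


class TestMatrixLevelFeatures:
    def test_all_ones(self):
        feats = matrix_level_features(st_from_matrix(np.ones((3, 4))))
        assert feats["max_freq_mean"] == pytest.approx(1.0)
        assert feats["mean_abs_dev"] == pytest.approx(0.0)

    def test_two_by_two_hand_arithmetic(self):
        feats = matrix_level_features(st_from_matrix([[1.0, 2.0], [3.0, 4.0]]))
        assert feats["max_freq_mean"] == pytest.approx(3.5)
        assert feats["mean_abs_dev"] == pytest.approx(1.0)

    def test_random_matrix_against_two_pass_oracle(self, rng):
        mag = rng.uniform(size=(9, 13))
        feats = matrix_level_features(st_from_matrix(mag))
        col_max_mean = sum(max(mag[:, j]) for j in range(13)) / 13
        grand = mag.sum() / mag.size
        mad = sum(abs(v - grand) for v in mag.ravel()) / mag.size
        assert feats["max_freq_mean"] == pytest.approx(col_max_mean)
        assert feats["mean_abs_dev"] == pytest.approx(mad)


class TestExtractEcgFeatures:
    def test_exactly_27_named_values_in_stable_order(self, small_window):
        feats = extract_ecg_features(stransform(small_window))
        assert tuple(feats) == ECG_FEATURE_NAMES
        assert len(feats) == 27

    def test_all_ones_matrix_na_pattern(self):
        feats = extract_ecg_features(st_from_matrix(np.ones((5, 8))))
        assert math.isnan(feats["std_f.log2_var"])
        assert math.isnan(feats["range_f.log2_var"])
        for name in ("mean_f.mean", "sum_f.sum", "product_f.mean"):
            assert math.isfinite(feats[name])

    def test_identical_windows_give_identical_features(self, rng):
        x = rng.normal(size=64)
        w1 = make_window(x.copy(), rate=6.4, duration=10.0)
        w2 = make_window(x.copy(), rate=6.4, duration=10.0)
        assert extract_ecg_features(stransform(w1)) == extract_ecg_features(stransform(w2))

    def test_scale_equivariance_of_reduced_series(self, rng):
        mag = rng.uniform(0.5, 1.5, size=(6, 10))
        c = 3.0
        base = reduce_over_frequency(st_from_matrix(mag))
        scaled = reduce_over_frequency(st_from_matrix(c * mag))
        for name in ("mean_f", "sum_f", "std_f", "range_f"):
            np.testing.assert_allclose(scaled[name], c * base[name], rtol=1e-9)
        np.testing.assert_allclose(
            scaled["product_f"], c**6 * base["product_f"], rtol=1e-9
        )

    def test_empty_matrix_rejected(self, small_window):
        st = stransform(small_window)
        st_dc_only = st_from_matrix(np.abs(st.values[:1]))
        with pytest.raises(ValidationError):
            reduce_over_frequency(st_dc_only, include_dc=False)
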