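import numpy as np
import pytest

from megdenoise import (
    estimate_n400m,
    fit_encoding,
    make_folds,
    power_by_word_length,
    surprisal_correlation,
    unique_variance_surprisal,
)

from conftest import make_dataset


class TestPowerByWordLength:
    def test_zero_data_zero_profiles(self):
        prof = power_by_word_length(np.zeros((30, 4, 6)), np.repeat([3, 5, 7], 10))
        np.testing.assert_array_equal(prof.profiles, 0.0)
        np.testing.assert_array_equal(prof.lengths, [3, 5, 7])
        np.testing.assert_array_equal(prof.group_sizes, [10, 10, 10])

    def test_single_group_equals_overall_mean_power(self):
        rng = np.random.default_rng(0)
        tensor = rng.standard_normal((25, 3, 4))
        prof = power_by_word_length(tensor, np.full(25, 6))
        np.testing.assert_allclose(prof.profiles[0], np.square(tensor).mean(axis=(0, 1)))

    def test_amplitude_proportional_to_length_orders_profiles(self):
        lengths = np.repeat(np.arange(2, 8), 40)
        kernel = np.exp(-0.5 * ((np.arange(10) - 5) / 2.0) ** 2)
        tensor = lengths[:, None, None] * kernel[None, None, :] * np.ones((1, 4, 1))
        tensor = tensor + 0.05 * np.random.default_rng(1).standard_normal(tensor.shape)
        prof = power_by_word_length(tensor, lengths)
        peak = int(prof.profiles.mean(axis=0).argmax())
        assert np.all(np.diff(prof.profiles[:, peak]) > 0)

    def test_event_mask_restricts_groups(self):
        tensor = np.ones((10, 2, 3))
        mask = np.zeros(10, bool)
        mask[:4] = True
        prof = power_by_word_length(tensor, [2] * 4 + [9] * 6, event_mask=mask)
        np.testing.assert_array_equal(prof.lengths, [2])

    def test_empty_sensor_selection_rejected(self):
        with pytest.raises(ValueError):
            power_by_word_length(np.zeros((5, 2, 3)), [1] * 5, sensor_subset=[])


class TestN400m:
    def test_single_sensor_region_equals_window_mean(self, tiny_dataset):
        ds = make_dataset(n_time=20)
        series = estimate_n400m(ds, "S1", region=[2], window_ms=(300.0, 500.0))
        bins = ds.time_window(300.0, 500.0)
        np.testing.assert_allclose(series.values, ds.data["S1"][:, 2, bins].mean(axis=1))

    def test_single_bin_window(self):
        ds = make_dataset(n_time=20)
        series = estimate_n400m(ds, "S1", region=[1, 3], window_ms=(400.0, 425.0))
        bin_idx = list(ds.time_axis).index(400.0)
        np.testing.assert_allclose(series.values, ds.data["S1"][:, [1, 3], bin_idx].max(axis=1))

    def test_region_label_resolution_and_abs(self):
        ds = make_dataset(n_sensors=6, n_time=20)
        signed = estimate_n400m(ds, "S1", "left-temporal")
        pooled = estimate_n400m(ds, "S1", "left-temporal", use_abs=True)
        assert np.all(pooled.values >= signed.values - 1e-12)

    def test_empty_region_rejected(self):
        ds = make_dataset(n_sensors=6, n_time=20)
        with pytest.raises(ValueError, match="no sensors"):
            estimate_n400m(ds, "S1", region=[])

    def test_window_convention_golden(self):
        """The 300-500 ms window maps to the 8 bins labelled 300..475 ms."""
        ds = make_dataset(n_time=20)
        bins = ds.time_window(300.0, 500.0)
        assert list(ds.time_axis[bins]) == [300, 325, 350, 375, 400, 425, 450, 475]


class TestSurprisalCorrelation:
    def test_affine_series_perfect_correlation(self):
        rng = np.random.default_rng(2)
        surp = rng.uniform(1, 9, 200)
        r, p = surprisal_correlation(2.5 * surp + 1.0, surp, n_perms=99, seed=0)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(1 / 100)

    def test_constant_surprisal_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            surprisal_correlation(np.random.default_rng(3).standard_normal(50),
                                  np.full(50, 4.0), n_perms=10)

    def test_recovers_analytic_effect_size(self):
        """series = beta*surprisal + noise recovers r = beta*sd(s)/sd(series)."""
        rng = np.random.default_rng(4)
        surp = rng.uniform(0, 10, 4000)
        beta, sigma = 0.4, 2.0
        series = beta * surp + sigma * rng.standard_normal(4000)
        r, p = surprisal_correlation(series, surp, n_perms=199, seed=1)
        expected = beta * surp.std() / series.std()
        assert abs(r - expected) < 3 / np.sqrt(4000)
        assert p == pytest.approx(1 / 200)

    def test_nan_events_excluded(self):
        rng = np.random.default_rng(5)
        surp = rng.uniform(0, 5, 100)
        series = np.where(np.arange(100) < 50, surp, np.nan)
        r, _ = surprisal_correlation(series, surp, n_perms=19, seed=0)
        assert r == pytest.approx(1.0)


class TestEncoding:
    def test_exact_linear_data_gives_unit_correlation(self):
        rng = np.random.default_rng(6)
        n = 300
        feats = np.column_stack([rng.integers(2, 10, n), rng.standard_normal(n),
                                 rng.uniform(0, 8, n)])
        maps = rng.standard_normal((3, 4 * 5))
        tensor = (feats @ maps).reshape(n, 4, 5)
        scheme = make_folds(n, n_blocks=3, n_edge_drop=5)
        res = fit_encoding(feats, tensor, scheme, lambda_grid=[1e-6])
        np.testing.assert_allclose(res.by_time(), 1.0, atol=1e-6)

    def test_shuffled_features_near_zero(self):
        rng = np.random.default_rng(7)
        n = 300
        feats = rng.standard_normal((n, 3))
        tensor = rng.standard_normal((n, 4, 5))
        scheme = make_folds(n, n_blocks=3, n_edge_drop=5)
        res = fit_encoding(feats, tensor, scheme)
        assert np.abs(res.by_time()).max() < 0.2

    def test_nan_features_rejected(self):
        feats = np.zeros((100, 3))
        feats[0, 0] = np.nan
        with pytest.raises(ValueError):
            fit_encoding(feats, np.zeros((100, 2, 3)), make_folds(100, n_blocks=2, n_edge_drop=4))


class TestUniqueVariance:
    @staticmethod
    def _encode_pair(beta_surp, seed):
        rng = np.random.default_rng(seed)
        n, n_sensors, n_time = 400, 3, 10
        length = rng.integers(2, 10, n).astype(float)
        freq = 3 - 0.3 * length + rng.standard_normal(n)
        surp = np.maximum(0.1, 6 - 0.7 * freq + rng.standard_normal(n))
        feats = np.column_stack([length, freq, surp])
        kernel = np.zeros(n_time)
        kernel[6:8] = 1.0  # late "semantic" bins
        tensor = (
            0.3 * length[:, None, None] * np.ones((1, n_sensors, 1))
            + beta_surp * surp[:, None, None] * kernel[None, None, :]
            + rng.standard_normal((n, n_sensors, n_time))
        )
        # 6 folds so the exact sign-flip null (2^k patterns) can reach p < 0.05
        scheme = make_folds(n, n_blocks=6, n_edge_drop=5)
        full = fit_encoding(feats, tensor, scheme)
        red = fit_encoding(feats[:, :2], tensor, scheme, feature_names=["length", "freq"])
        return full, red

    def test_planted_surprisal_effect_peaks_at_planted_bins(self):
        full, red = self._encode_pair(beta_surp=0.6, seed=8)
        uv = unique_variance_surprisal(full, red)
        assert uv["peak_bin"] in (6, 7)
        assert uv["difference_by_time"][uv["peak_bin"]] > 0.05
        assert uv["significant"][uv["peak_bin"]]

    def test_null_effect_rate_bounded(self):
        rates = []
        for seed in range(4):
            full, red = self._encode_pair(beta_surp=0.0, seed=20 + seed)
            uv = unique_variance_surprisal(full, red)
            rates.append(uv["significant"].mean())
        assert np.mean(rates) <= 0.05
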