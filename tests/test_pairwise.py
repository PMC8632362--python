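import numpy as np
import pytest

from megdenoise import (
    SGTG,
    KvConfig,
    PredictorSetting,
    build_predictors,
    denoise_pm,
    fit_pairwise,
    flatten,
    heldout_accuracy,
    make_folds,
    predict_heldout,
)
from megdenoise.data_model import MultiSubjectDataset

from conftest import make_dataset, make_sensor_table


def _clone_with(ds, data):
    return MultiSubjectDataset(list(ds.subjects), data, ds.time_axis.copy(), ds.sensors, list(ds.runs))


class TestBuildPredictors:
    def test_global_global_covers_everything(self):
        sensors = make_sensor_table(6)
        sens, times = build_predictors(SGTG, sensors, 20, (3, 7))
        assert len(sens) * len(times) == 120

    def test_most_local_case_is_the_matched_point(self):
        sensors = make_sensor_table(6)
        setting = PredictorSetting("local", "local", k_sensors=1, half_width=0)
        sens, times = build_predictors(setting, sensors, 20, (4, 9))
        assert list(sens) == [4] and list(times) == [9]

    def test_temporal_window_clips_at_epoch_edges(self):
        sensors = make_sensor_table(6)
        setting = PredictorSetting("global", "local", half_width=1)
        _, times = build_predictors(setting, sensors, 20, (0, 0))
        assert list(times) == [0, 1]
        _, times = build_predictors(setting, sensors, 20, (0, 19))
        assert list(times) == [18, 19]

    def test_local_neighborhood_contains_own_sensor(self):
        sensors = make_sensor_table(10)
        setting = PredictorSetting("local", "global", k_sensors=3)
        for s in range(10):
            sens, _ = build_predictors(setting, sensors, 5, (s, 0))
            assert s in sens


class TestFitPairwise:
    def test_self_map_identity_recovers_target(self):
        ds = make_dataset(n_subjects=2, n_events=240, n_sensors=5, n_time=4, seed=1)
        ds.data["S2"] = ds.data["S1"].copy()
        scheme = make_folds(240, n_blocks=2, n_edge_drop=10)
        model = fit_pairwise(ds, "S1", "S2", scheme, SGTG, lambda_grid=[1e-6])
        pred = predict_heldout(model, ds)
        gold = flatten(ds, "S2").values
        acc = heldout_accuracy(pred, gold, scheme, KvConfig(K=20, n_draws=500, seed=0))
        assert acc > 0.99

    def test_independent_subjects_stay_at_chance(self):
        """Null simulation: with no shared signal the mean 20v40 is 0.5.

        A single dataset realisation is not enough: at K=20 the statistic
        amplifies whatever in-sample covariance the finite test fold happened
        to realise (sd ~ 0.1 at this size), so the null holds in expectation
        over datasets, not per dataset.
        """
        accs = []
        for seed in range(10):
            ds = make_dataset(n_subjects=2, n_events=600, n_sensors=4, n_time=4, seed=seed)
            scheme = make_folds(600, n_blocks=2, n_edge_drop=10)
            pred = predict_heldout(fit_pairwise(ds, "S1", "S2", scheme), ds)
            accs.append(
                heldout_accuracy(pred, flatten(ds, "S2").values, scheme,
                                 KvConfig(K=20, n_draws=600, seed=0))
            )
        assert abs(np.mean(accs) - 0.5) < 0.07

    def test_infinite_penalty_predicts_training_mean(self):
        ds = make_dataset(n_subjects=2, n_events=200, n_sensors=3, n_time=3, seed=3)
        scheme = make_folds(200, n_blocks=2, n_edge_drop=5)
        model = fit_pairwise(ds, "S1", "S2", scheme, lambda_grid=[1e12])
        pred = predict_heldout(model, ds)
        train, test = (np.flatnonzero(scheme.fold_id != 0), np.flatnonzero((scheme.fold_id == 0) & scheme.test_usable))
        target_mean = flatten(ds, "S2").values[train].mean(axis=0)
        np.testing.assert_allclose(pred[test], np.tile(target_mean, (len(test), 1)), atol=1e-3)

    def test_nan_input_rejected(self):
        ds = make_dataset(n_subjects=2, n_events=100, seed=4)
        ds.data["S1"][0, 0, 0] = np.nan
        scheme = make_folds(100, n_blocks=2, n_edge_drop=2)
        with pytest.raises(ValueError, match="NaN"):
            fit_pairwise(ds, "S1", "S2", scheme)

    def test_heldout_discipline(self):
        """Zeroing a test fold's target data never changes that fold's predictions."""
        ds = make_dataset(n_subjects=2, n_events=200, n_sensors=4, n_time=3, seed=5)
        scheme = make_folds(200, n_blocks=2, n_edge_drop=5)
        pred_a = predict_heldout(fit_pairwise(ds, "S1", "S2", scheme), ds)
        _, test0 = np.flatnonzero(scheme.fold_id != 0), np.flatnonzero(scheme.fold_id == 0)
        tampered = {s: d.copy() for s, d in ds.data.items()}
        tampered["S2"][test0] = 0.0
        pred_b = predict_heldout(fit_pairwise(_clone_with(ds, tampered), "S1", "S2", scheme), ds)
        usable0 = (scheme.fold_id == 0) & scheme.test_usable
        np.testing.assert_allclose(pred_a[usable0], pred_b[usable0])


class TestDenoise:
    def test_two_subjects_mean_of_one_source(self):
        ds = make_dataset(n_subjects=2, n_events=200, n_sensors=4, n_time=3, seed=6)
        scheme = make_folds(200, n_blocks=2, n_edge_drop=5)
        den = denoise_pm(ds, scheme, keep_pairwise=True)
        pair = den.pairwise[("S2", "S1")]
        avg = flatten(den.dataset, "S2").values
        mask = scheme.test_usable
        np.testing.assert_allclose(avg[mask], pair[mask])

    def test_identical_sources_average_to_each(self):
        ds = make_dataset(n_subjects=3, n_events=200, n_sensors=4, n_time=3, seed=7)
        ds.data["S3"] = ds.data["S2"].copy()
        scheme = make_folds(200, n_blocks=2, n_edge_drop=5)
        den = denoise_pm(ds, scheme, keep_pairwise=True)
        mask = scheme.test_usable
        a = den.pairwise[("S1", "S2")][mask]
        b = den.pairwise[("S1", "S3")][mask]
        np.testing.assert_allclose(a, b, atol=1e-8)
        np.testing.assert_allclose(flatten(den.dataset, "S1").values[mask], a, atol=1e-8)

    def test_single_subject_rejected(self):
        ds = make_dataset(n_subjects=1, n_events=100, seed=8)
        scheme = make_folds(100, n_blocks=2, n_edge_drop=2)
        with pytest.raises(ValueError, match="2 subjects"):
            denoise_pm(ds, scheme)

    def test_affine_equivariance(self):
        """Scaling and shifting all subjects maps the denoised output the same way."""
        ds = make_dataset(n_subjects=2, n_events=200, n_sensors=3, n_time=3, seed=9)
        scheme = make_folds(200, n_blocks=2, n_edge_drop=5)
        den = denoise_pm(ds, scheme)
        moved = _clone_with(ds, {s: 3.0 * d + 1.5 for s, d in ds.data.items()})
        den2 = denoise_pm(moved, scheme)
        mask = scheme.test_usable
        np.testing.assert_allclose(
            den2.dataset.data["S1"][mask], 3.0 * den.dataset.data["S1"][mask] + 1.5, rtol=1e-6, atol=1e-6
        )

    def test_values_only_at_test_usable_events(self):
        ds = make_dataset(n_subjects=2, n_events=200, seed=10)
        scheme = make_folds(200, n_blocks=2, n_edge_drop=8)
        den = denoise_pm(ds, scheme)
        assert np.isnan(den.dataset.data["S1"][~scheme.test_usable]).all()
        assert not np.isnan(den.dataset.data["S1"][scheme.test_usable]).any()

    def test_denoising_recovers_planted_shared_signal(self, small_sim):
        """Correlation with the shared response rises after denoising."""
        cfg, ds, stim, shared, scheme = small_sim
        den = denoise_pm(ds, scheme)
        mask = scheme.test_usable
        flat_shared = shared.reshape(len(shared), -1)

        def mean_corr(tensor):
            flat = tensor.reshape(len(tensor), -1)
            a = flat[mask] - flat[mask].mean(0)
            b = flat_shared[mask] - flat_shared[mask].mean(0)
            denom = np.sqrt((a**2).sum(0) * (b**2).sum(0))
            return float(np.mean((a * b).sum(0) / denom))

        r_orig = np.mean([mean_corr(ds.data[s]) for s in ds.subjects])
        r_den = np.mean([mean_corr(den.dataset.data[s]) for s in ds.subjects])
        assert r_den > r_orig
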