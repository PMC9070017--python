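"""Balanced accuracy, feature extraction, model evaluation, window
tuning and the RDA/KDE reference classifier."""

import numpy as np
import pytest

from rsvp_alpha.classify import (CVSpec, FeatureMatrix, balanced_accuracy,
                                 epoch_covariances, extract_alpha_features,
                                 geometric_mean, make_window_grid,
                                 rda_kde_eval, tangent_vectors, train_eval,
                                 tune_windows)
from rsvp_alpha.preprocess import EpochSet
from rsvp_alpha.sim import NONTARGET, TARGET
from rsvp_alpha.tf_alpha import Scaleogram

CV3 = CVSpec(n_reps=3)


def _imbalanced_labels(n=1000, ratio=9):
    y = np.zeros(n, dtype=int)
    y[::ratio + 1] = 1
    return y


class TestBalancedAccuracy:
    def test_perfect_predictions(self):
        y = _imbalanced_labels(100)
        assert balanced_accuracy(y, y) == 1.0

    def test_majority_vote_scores_half_on_imbalanced_data(self):
        y = _imbalanced_labels(100)
        assert balanced_accuracy(y, np.zeros_like(y)) == 0.5

    def test_mean_of_per_class_recalls(self):
        # recalls 0.6 (targets) and 0.8 (non-targets) -> 0.7
        y = np.array([1] * 10 + [0] * 10)
        pred = np.array([1] * 6 + [0] * 4 + [0] * 8 + [1] * 2)
        assert balanced_accuracy(y, pred) == pytest.approx(0.7)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            balanced_accuracy(np.zeros(10), np.zeros(10))


def _zscaleogram(rng, n_epochs=200, n_ch=4, n_samp=375, shift=0.0):
    """Z-unit scaleogram with an optional target-class mean shift in the
    response window."""
    data = rng.standard_normal((n_epochs, n_ch, 1, n_samp))
    labels = np.array([TARGET if i % 10 == 0 else NONTARGET
                       for i in range(n_epochs)], dtype=object)
    sl = slice(232, 307)                       # 300..800 ms at 150 Hz
    data[labels == TARGET, :, :, sl] += shift
    return Scaleogram(data=data, layer_freqs=np.array([10.0]),
                      units="zscore", window_ms=(-1250.0, 1250.0),
                      fs=150.0, labels=labels,
                      channels=("Pz", "Oz", "PO7", "PO8"),
                      baseline_window_ms=(-600.0, -100.0))


class TestFeatures:
    def test_feature_dimensions(self):
        rng = np.random.default_rng(0)
        sc = _zscaleogram(rng, n_epochs=50)
        f = extract_alpha_features(sc, 0, (300.0, 800.0))
        # 500 ms at 150 Hz = 75 samples x 4 channels = 300 features
        assert f.X.shape == (50, 300)
        assert f.series.shape == (50, 4, 75)

    def test_zero_input_gives_zero_features(self):
        sc = _zscaleogram(np.random.default_rng(0), n_epochs=20)
        sc.data[:] = 0.0
        f = extract_alpha_features(sc, 0, (300.0, 800.0))
        assert np.all(f.X == 0)

    def test_magnitude_input_rejected(self):
        sc = _zscaleogram(np.random.default_rng(0), n_epochs=20)
        sc.units = "magnitude_uV"
        with pytest.raises(ValueError):
            extract_alpha_features(sc, 0, (300.0, 800.0))


class TestTrainEval:
    def test_uniform_random_is_at_chance(self):
        rng = np.random.default_rng(1)
        y = _imbalanced_labels(1000)
        f = FeatureMatrix(X=rng.standard_normal((1000, 5)), y=y)
        res = train_eval(f, "uniform_random", cv=CVSpec(n_reps=10), seed=0)
        assert res.mean_balanced_acc == pytest.approx(0.5, abs=0.05)

    def test_oracle_is_perfect(self):
        rng = np.random.default_rng(1)
        y = _imbalanced_labels(500)
        f = FeatureMatrix(X=rng.standard_normal((500, 3)), y=y)
        res = train_eval(f, "oracle", cv=CV3, seed=0)
        assert res.mean_balanced_acc == 1.0

    def test_separable_features_classified_perfectly(self):
        y = _imbalanced_labels(400)
        X = np.column_stack([y * 10.0 - 5.0,
                             np.random.default_rng(2).standard_normal(400)])
        res = train_eval(FeatureMatrix(X=X, y=y), "logreg_l2", cv=CV3,
                         seed=0)
        assert res.mean_balanced_acc == 1.0

    def test_shifted_scaleogram_classes_separable_by_all_models(self):
        rng = np.random.default_rng(3)
        sc = _zscaleogram(rng, n_epochs=400, shift=-1.5)
        f = extract_alpha_features(sc, 0, (300.0, 800.0))
        for model in ("logreg_l2", "svc", "tangent_space"):
            res = train_eval(f, model, cv=CV3, seed=1)
            assert res.mean_balanced_acc > 0.55, model

    def test_label_shuffle_restores_chance(self):
        rng = np.random.default_rng(4)
        sc = _zscaleogram(rng, n_epochs=400, shift=-1.5)
        f = extract_alpha_features(sc, 0, (300.0, 800.0))
        f_shuf = FeatureMatrix(X=f.X, y=rng.permutation(f.y),
                               series=f.series)
        res = train_eval(f_shuf, "logreg_l2", cv=CVSpec(n_reps=10), seed=2)
        assert res.mean_balanced_acc == pytest.approx(0.5, abs=0.07)

    def test_identical_seed_identical_splits(self):
        rng = np.random.default_rng(5)
        y = _imbalanced_labels(300)
        f = FeatureMatrix(X=rng.standard_normal((300, 10)), y=y)
        a = train_eval(f, "logreg_l2", cv=CV3, seed=9)
        b = train_eval(f, "logreg_l2", cv=CV3, seed=9)
        assert a.per_split_balanced_acc == b.per_split_balanced_acc


class TestTangentSpaceGeometry:
    def test_geometric_mean_of_identical_matrices(self):
        covs = np.tile(np.diag([2.0, 3.0]), (5, 1, 1))
        np.testing.assert_allclose(geometric_mean(covs),
                                   np.diag([2.0, 3.0]), atol=1e-8)

    def test_tangent_vector_at_reference_is_zero(self):
        c = np.diag([2.0, 5.0])
        vec = tangent_vectors(c[None], c)
        np.testing.assert_allclose(vec, 0.0, atol=1e-10)

    def test_covariances_are_positive_definite(self):
        rng = np.random.default_rng(6)
        series = rng.standard_normal((20, 4, 75))
        covs = epoch_covariances(series)
        assert np.all(np.linalg.eigvalsh(covs) > 0)


class TestWindowTuning:
    def test_default_grid_has_90_points(self):
        b, r = make_window_grid(step_ms=50.0)
        assert b.size == 10 and r.size == 9
        assert b[0] == -1050.0 and b[-1] == -600.0
        assert r[0] == 150.0 and r[-1] == 550.0

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            make_window_grid(step_ms=-10.0)

    def _mag_scaleogram(self, response_center_ms, n_epochs=300, seed=0):
        """Magnitude scaleogram whose target epochs dip at a known
        latency."""
        rng = np.random.default_rng(seed)
        n_samp = 375
        fs = 150.0
        times = (np.arange(n_samp) - 187) / fs * 1000.0
        data = 10.0 + rng.standard_normal((n_epochs, 4, 1, n_samp))
        labels = np.array([TARGET if i % 10 == 0 else NONTARGET
                           for i in range(n_epochs)], dtype=object)
        dip = 4.0 * np.exp(-0.5 * ((times - response_center_ms) / 150.0) ** 2)
        data[labels == TARGET] -= dip[None, None, None, :]
        return Scaleogram(data=data, layer_freqs=np.array([10.0]),
                          units="magnitude_uV", window_ms=(-1250.0, 1250.0),
                          fs=fs, labels=labels,
                          channels=("Pz", "Oz", "PO7", "PO8"))

    def test_grid_scores_and_argmax_dominance(self):
        sc = self._mag_scaleogram(response_center_ms=550.0)
        grid = tune_windows(sc, grid_step_ms=150.0, cv=CVSpec(n_reps=3),
                            seed=1, nested=False)
        assert grid.scores.shape == (4, 3)
        bi = list(grid.baseline_starts_ms).index(grid.best[0])
        bj = list(grid.response_starts_ms).index(grid.best[1])
        assert grid.scores[bi, bj] == grid.scores.max()
        # default pair is on this grid; tuned score dominates it
        i0 = list(grid.baseline_starts_ms).index(-600.0)
        j0 = list(grid.response_starts_ms).index(300.0)
        assert grid.scores.max() >= grid.scores[i0, j0]

    def test_late_effect_moves_best_response_start_late(self):
        sc = self._mag_scaleogram(response_center_ms=700.0, seed=3)
        grid = tune_windows(sc, grid_step_ms=200.0, cv=CVSpec(n_reps=3),
                            seed=2, nested=True)
        assert grid.best[1] > 300.0

    def test_requires_single_layer_magnitude(self):
        rng = np.random.default_rng(1)
        sc = _zscaleogram(rng, n_epochs=30)
        with pytest.raises(ValueError):
            tune_windows(sc, cv=CV3, seed=0)


class TestRdaKde:
    def _erp_epochs(self, n=300, separable=True, seed=0):
        rng = np.random.default_rng(seed)
        data = rng.standard_normal((n, 7, 75))
        labels = np.array([TARGET if i % 10 == 0 else NONTARGET
                           for i in range(n)], dtype=object)
        if separable:
            bump = np.exp(-0.5 * ((np.arange(75) - 50) / 6.0) ** 2)
            data[labels == TARGET, 2, :] += 6.0 * bump
        return EpochSet(data=data, window_ms=(0.0, 500.0), fs=150.0,
                        labels=labels,
                        channels=("FCz", "F7", "Pz", "P4", "PO7", "PO8",
                                  "Oz"))

    def test_separable_erp_classified_above_chance(self):
        res = rda_kde_eval(self._erp_epochs(), cv=CV3, seed=0)
        assert res.mean_balanced_acc > 0.8

    def test_label_shuffle_is_at_chance(self):
        eps = self._erp_epochs(n=400, separable=False, seed=5)
        res = rda_kde_eval(eps, cv=CVSpec(n_reps=10), seed=1)
        assert res.mean_balanced_acc == pytest.approx(0.5, abs=0.07)

    def test_zero_variance_input_rejected(self):
        eps = self._erp_epochs()
        eps.data[:] = 0.0
        with pytest.raises(ValueError):
            rda_kde_eval(eps, cv=CV3, seed=0)
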