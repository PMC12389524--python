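import numpy as np
import pandas as pd
import pytest

from mixqsar.datasets import DescriptorTable, load_reference_predictions
from mixqsar.errors import DataError
from mixqsar.validation import (
    ccc,
    compare_reference_statistics,
    leverage,
    q2_kfold,
    q2_loo,
    qf_metrics,
    r_squared,
    rmse,
    validation_report,
    warning_leverage,
    williams_report,
    y_randomization,
)


class MeanPredictor:
    def __init__(self, X, y):
        self.mean = float(np.mean(y))

    def predict(self, X):
        return np.full(len(np.atleast_2d(X)), self.mean)


class OLSPredictor:
    def __init__(self, X, y):
        design = np.column_stack([np.ones(len(y)), np.atleast_2d(X)])
        self.beta, *_ = np.linalg.lstsq(design, y, rcond=None)

    def predict(self, X):
        design = np.column_stack([np.ones(len(np.atleast_2d(X))), np.atleast_2d(X)])
        return design @ self.beta


def make_table(X, y, flags=None):
    X = np.atleast_2d(X)
    return DescriptorTable(
        [f"c{i}" for i in range(len(y))],
        pd.DataFrame({f"d{j}": X[:, j] for j in range(X.shape[1])}),
        np.asarray(y, dtype=float),
        flags,
    )


class TestPointMetrics:
    def test_perfect_predictions(self, rng):
        y = rng.standard_normal(10)
        assert r_squared(y, y) == pytest.approx(1.0)
        assert rmse(y, y) == 0.0
        assert ccc(y, y) == pytest.approx(1.0)
        qf1, qf2 = qf_metrics(y, y, y.mean() + 1.0)
        assert (qf1, qf2) == (1.0, 1.0)

    def test_mean_prediction_gives_zero_r2(self, rng):
        y = rng.standard_normal(10)
        assert r_squared(y, np.full(10, y.mean())) == pytest.approx(0.0)

    def test_rmse_hand_value(self):
        assert rmse([0.0, 2.0], [0.0, 0.0]) == pytest.approx(np.sqrt(2.0))

    def test_ccc_reversed_sequence_is_minus_one(self):
        assert ccc([1.0, 2.0, 3.0], [3.0, 2.0, 1.0]) == pytest.approx(-1.0)

    def test_ccc_penalizes_location_shift_below_pearson(self, rng):
        y = rng.standard_normal(20)
        shifted = y + 2.0
        assert ccc(y, shifted) < 1.0
        assert abs(ccc(y, shifted)) <= abs(np.corrcoef(y, shifted)[0, 1])

    def test_ccc_bounded_by_pearson_on_random_pairs(self, rng):
        for _ in range(25):
            y = rng.standard_normal(15)
            yhat = rng.standard_normal(15)
            assert abs(ccc(y, yhat)) <= abs(np.corrcoef(y, yhat)[0, 1]) + 1e-12

    def test_qf_hand_example_and_equal_means_case(self):
        qf1, qf2 = qf_metrics([0.0, 1.0], [0.0, 0.0], 0.5)
        assert qf1 == pytest.approx(-1.0)
        assert qf2 == pytest.approx(-1.0)

    def test_r2_affine_invariance(self, rng):
        y = rng.standard_normal(12)
        yhat = y + 0.3 * rng.standard_normal(12)
        a, b = 2.7, -1.1
        assert r_squared(a * y + b, a * yhat + b) == pytest.approx(r_squared(y, yhat))

    def test_constant_y_rejected(self):
        with pytest.raises(DataError):
            r_squared([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestCrossValidatedQ2:
    def test_mean_predictor_matches_closed_form(self, rng):
        """LOO with the train-mean predictor has PRESS = (n/(n-1))^2 SST,
        hence Q^2 = 1 - (n/(n-1))^2 exactly."""
        y = rng.standard_normal(12)
        table = make_table(rng.standard_normal((12, 2)), y)
        n = 12
        expected = 1.0 - (n / (n - 1)) ** 2
        assert q2_loo(MeanPredictor, table) == pytest.approx(expected)

    def test_exact_model_class_reaches_one(self, linear_table):
        table, _ = linear_table
        assert q2_loo(OLSPredictor, table) == pytest.approx(1.0, abs=1e-8)

    def test_kfold_equals_loo_when_k_is_n(self, rng):
        y = rng.standard_normal(10)
        table = make_table(rng.standard_normal((10, 2)), y)
        assert q2_kfold(OLSPredictor, table, k=10, seed=0) == pytest.approx(
            q2_loo(OLSPredictor, table)
        )

    def test_kfold_deterministic_under_seed(self, rng):
        y = rng.standard_normal(20)
        table = make_table(rng.standard_normal((20, 2)), y)
        a = q2_kfold(OLSPredictor, table, k=5, seed=3)
        b = q2_kfold(OLSPredictor, table, k=5, seed=3)
        assert a == b


class TestYRandomization:
    def test_mean_factory_gives_zero_r2(self, rng):
        y = rng.standard_normal(15)
        table = make_table(rng.standard_normal((15, 2)), y)
        results = y_randomization(MeanPredictor, table, n_repeats=3, seed=0)
        assert all(r2 == pytest.approx(0.0) for r2, _ in results)

    def test_strong_signal_survives_scrambling_check(self):
        """Real fit R^2 ~ 1 while permuted refits stay below 0.3."""
        rng = np.random.default_rng(0)
        X = rng.standard_normal((100, 4))
        y = X @ np.array([1.5, -2.0, 1.0, 0.5]) + 0.1 * rng.standard_normal(100)
        table = make_table(X, y)
        real = OLSPredictor(X, y)
        real_r2 = r_squared(y, real.predict(X))
        results = y_randomization(OLSPredictor, table, n_repeats=10, seed=1)
        assert real_r2 > 0.9
        assert max(r2 for r2, _ in results) < 0.3

    def test_seeded_repeatability(self, rng):
        y = rng.standard_normal(20)
        table = make_table(rng.standard_normal((20, 2)), y)
        a = y_randomization(OLSPredictor, table, n_repeats=5, seed=7)
        b = y_randomization(OLSPredictor, table, n_repeats=5, seed=7)
        assert a == b


class TestLeverageAndWilliams:
    def test_training_leverages_sum_to_parameter_count(self, rng):
        X = np.column_stack([np.ones(10), rng.standard_normal((10, 2))])
        h = leverage(X)
        assert h.sum() == pytest.approx(3.0)

    def test_query_at_mean_of_centered_descriptor_has_h_equal_1_over_n(self, rng):
        x = rng.standard_normal(20)
        x = x - x.mean()
        X = np.column_stack([np.ones(20), x])
        h = leverage(X, np.array([[1.0, 0.0]]))
        assert h[0] == pytest.approx(1.0 / 20)

    def test_matches_hat_matrix_diagonal(self, rng):
        X = rng.standard_normal((10, 3))
        H = X @ np.linalg.inv(X.T @ X) @ X.T
        np.testing.assert_allclose(leverage(X), np.diag(H), atol=1e-10)

    def test_warning_leverage_formula(self):
        assert warning_leverage(5, 73) == pytest.approx(15.0 / 73.0)
        assert warning_leverage(5, 73) == pytest.approx(0.20548, abs=1e-5)

    def test_single_large_residual_is_the_only_outlier(self, rng):
        X = rng.standard_normal((30, 2))
        y = X[:, 0].copy()
        flags = np.array(["train"] * 30, dtype=object)
        table = make_table(X, y, flags)
        preds = y.copy()
        noise = rng.standard_normal(30) * 0.01
        preds = y + noise
        preds[4] = y[4] + 40 * np.abs(noise).mean()  # far beyond 3 sd
        report = williams_report(table, preds)
        assert report.counts["response_outlier"] == 1
        assert report.classification[4] == "response_outlier"

    def test_far_query_point_is_high_leverage(self, rng):
        X_train = rng.standard_normal((40, 2))
        X_far = np.array([[15.0, -12.0]])
        X = np.vstack([X_train, X_far])
        y = np.concatenate([X_train[:, 0], [15.0]])
        flags = np.array(["train"] * 40 + ["test"], dtype=object)
        table = make_table(X, y, flags)
        preds = y + 0.01 * rng.standard_normal(41)
        report = williams_report(table, preds)
        assert report.leverages[-1] > report.h_star
        assert report.classification[-1] == "influential"
        # oracle: explicit hat-matrix diagonal for the training block
        design = np.column_stack([np.ones(40), X_train])
        H = design @ np.linalg.inv(design.T @ design) @ design.T
        np.testing.assert_allclose(report.leverages[:40], np.diag(H), atol=1e-10)


class TestAggregateReports:
    def test_validation_report_contains_full_battery(self, linear_table):
        table, _ = linear_table
        from mixqsar.datasets import split_train_test

        table = split_train_test(table, 0.25, seed=2)
        report = validation_report(OLSPredictor, table, k=5, seed=0)
        assert report.r2_train == pytest.approx(1.0)
        assert report.q2_loo == pytest.approx(1.0, abs=1e-8)
        assert report.r2_test == pytest.approx(1.0)
        assert report.passes["ccc"]
        payload = report.to_dict()
        assert set(payload) >= {"r2_train", "q2_loo", "q2_5fold", "ccc", "qf1", "qf2"}

    def test_reference_table_only_mix_svm_matches_published_summary(self):
        frame = compare_reference_statistics(tolerance=0.002)
        matches = dict(zip(frame["model"], frame["match"]))
        assert matches["mix_svm"] is True or matches["mix_svm"] == True  # noqa: E712
        for other in ("hm", "rf", "gep", "gbdt", "poly_svm"):
            assert not matches[other]

    def test_reference_mix_svm_statistics_reproduce_published_values(self):
        ref = load_reference_predictions()
        y, pred, test = ref.measured, ref.predicted("mix_svm"), ref.is_test
        assert r_squared(y[test], pred[test]) == pytest.approx(0.9490, abs=0.002)
        assert rmse(y[test], pred[test]) == pytest.approx(0.1814, abs=0.002)
        assert r_squared(y[~test], pred[~test]) == pytest.approx(0.9445, abs=0.002)
        assert rmse(y[~test], pred[~test]) == pytest.approx(0.1659, abs=0.002)
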