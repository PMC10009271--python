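import numpy as np
import pytest

from nircal.exceptions import DataError, DegenerateDataError, SizeError
from nircal.pls import (
    fit_pls,
    kfold_rmsecv,
    loo_rmsecv,
    predict,
    regression_metrics,
)


def ols_predictions(X, y, X_new):
    A = np.column_stack([np.ones(len(y)), X])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    return coef[0] + X_new @ coef[1:]


class TestFitPredict:
    def test_proportional_data_exact(self):
        X = np.array([[1.0], [2.0], [3.0]])
        y = np.array([2.0, 4.0, 6.0])
        model = fit_pls(X, y, 1)
        assert abs(model.intercept_b0) < 1e-12
        assert np.allclose(model.coefficients_b, [2.0])
        assert np.allclose(predict(model, X).y_hat, y)

    def test_full_rank_equals_ols(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            X = rng.normal(size=(30, 5))
            y = X @ rng.normal(size=5) + rng.normal(size=30)
            model = fit_pls(X, y, 5)
            assert np.max(np.abs(predict(model, X).y_hat - ols_predictions(X, y, X))) < 1e-8

    def test_matches_sklearn_nipals(self):
        """NIPALS vs the reference PLS implementation: identical predictions."""
        from sklearn.cross_decomposition import PLSRegression

        rng = np.random.default_rng(11)
        X = rng.normal(size=(25, 12))
        y = X[:, :3] @ [1.0, -2.0, 0.5] + rng.normal(size=25) * 0.1
        for n_lv in (1, 3, 6):
            ours = predict(fit_pls(X, y, n_lv), X).y_hat
            theirs = PLSRegression(n_components=n_lv, scale=False).fit(X, y).predict(X).ravel()
            assert np.max(np.abs(ours - theirs)) < 1e-8

    def test_constant_target_rejected(self, rng):
        with pytest.raises(DegenerateDataError):
            fit_pls(rng.normal(size=(5, 3)), np.full(5, 7.0), 1)

    def test_excessive_components_rejected(self, rng):
        with pytest.raises(SizeError):
            fit_pls(rng.normal(size=(5, 10)), rng.normal(size=5), 5)

    def test_all_zero_X_predicts_intercept(self, rng):
        X = rng.normal(size=(10, 4))
        y = rng.normal(size=10) + 78
        model = fit_pls(X, y, 2)
        out = predict(model, np.zeros((3, 4)))
        assert np.allclose(out.y_hat, model.intercept_b0)

    def test_wrong_column_count_rejected(self, rng):
        model = fit_pls(rng.normal(size=(10, 4)), rng.normal(size=10), 2)
        with pytest.raises(DataError):
            predict(model, rng.normal(size=(3, 5)))

    def test_residuals_complement_predictions(self, rng):
        X = rng.normal(size=(12, 4))
        y = rng.normal(size=12)
        model = fit_pls(X, y, 3)
        out = predict(model, X, y=y)
        assert np.allclose(out.y_hat + out.residuals_e, y)

    def test_score_space_prediction_consistent(self, rng):
        """Folded-back (b0, b) agree with prediction through the scores."""
        X = rng.normal(size=(15, 6))
        y = rng.normal(size=15) + 78
        model = fit_pls(X, y, 4)
        dec = model.decomposition
        # scores T reproduce the fitted part of centred y
        y_hat_scores = model.y_mean + dec.scores_T @ dec.y_loadings_Q
        assert np.max(np.abs(predict(model, X).y_hat - y_hat_scores)) < 1e-10

    def test_score_orthogonality_and_residual_decay(self, rng):
        X = rng.normal(size=(20, 8))
        y = X @ rng.normal(size=8) + rng.normal(size=20) * 0.1
        model = fit_pls(X, y, 6)
        T = model.decomposition.scores_T
        gram = T.T @ T
        off = gram - np.diag(np.diag(gram))
        assert np.max(np.abs(off)) < 1e-8
        # in-sample RMSE non-increasing in the number of components
        rmses = [
            np.sqrt(np.mean((y - predict(fit_pls(X, y, lv), X).y_hat) ** 2))
            for lv in range(1, 7)
        ]
        assert all(a >= b - 1e-12 for a, b in zip(rmses, rmses[1:]))

    def test_model_dict_roundtrip(self, rng):
        X = rng.normal(size=(10, 5))
        y = rng.normal(size=10) + 78
        model = fit_pls(X, y, 3)
        from nircal.pls import PLSModel

        clone = PLSModel.from_dict(model.to_dict())
        assert np.allclose(predict(clone, X).y_hat, predict(model, X).y_hat)


def brute_force_loo(X, y, max_lv):
    m = X.shape[0]
    errs = np.empty((m, max_lv))
    for i in range(m):
        mask = np.ones(m, bool)
        mask[i] = False
        for lv in range(1, max_lv + 1):
            model = fit_pls(X[mask], y[mask], lv, keep_decomposition=False)
            errs[i, lv - 1] = y[i] - predict(model, X[i : i + 1]).y_hat[0]
    return np.sqrt(np.mean(errs**2, axis=0))


class TestLooRmsecv:
    def test_matches_brute_force_refits(self, rng):
        X = rng.normal(size=(12, 6))
        y = X @ rng.normal(size=6) + rng.normal(size=12) * 0.2
        ours, lv = loo_rmsecv(X, y, 4)
        oracle = brute_force_loo(X, y, 4)
        assert np.max(np.abs(ours - oracle)) < 1e-10
        assert lv == int(np.argmin(oracle)) + 1

    def test_noiseless_single_factor(self, rng):
        t = rng.normal(size=20)
        X = np.outer(t, rng.normal(size=8))
        y = 3.0 * t + 78
        rmsecv, lv = loo_rmsecv(X, y, 3)
        assert rmsecv[0] < 1e-8
        assert lv == 1

    def test_excess_max_lv_capped_with_warning(self, rng, caplog):
        X = rng.normal(size=(5, 6))
        y = rng.normal(size=5)
        with caplog.at_level("WARNING", logger="nircal.pls"):
            rmsecv, _ = loo_rmsecv(X, y, 10)
        assert rmsecv.size == 3  # min(m-2, n)
        assert any("capped" in r.message for r in caplog.records)

    def test_kfold_deterministic(self, rng):
        X = rng.normal(size=(20, 6))
        y = rng.normal(size=20)
        a, _ = kfold_rmsecv(X, y, 4, n_folds=5)
        b, _ = kfold_rmsecv(X, y, 4, n_folds=5)
        assert np.array_equal(a, b)


class TestRegressionMetrics:
    def test_perfect_prediction(self):
        m = regression_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert m.r_as_printed == pytest.approx(1.0)
        assert m.rmse == pytest.approx(0.0)

    def test_hand_computed_flat_prediction(self):
        # y=[1,2,3], yhat=[2,2,2]: SSres=2, SStot=2 -> R=0, RMSE=sqrt(2/3)
        m = regression_metrics([1.0, 2.0, 3.0], [2.0, 2.0, 2.0])
        assert m.r_as_printed == pytest.approx(0.0, abs=1e-12)
        assert m.rmse == pytest.approx(np.sqrt(2.0 / 3.0), rel=1e-12)

    def test_constant_actual_rejected(self):
        with pytest.raises(DegenerateDataError):
            regression_metrics([5.0, 5.0, 5.0], [5.0, 5.1, 4.9])

    def test_pearson_reported_alongside(self, rng):
        y = rng.normal(size=30)
        yhat = y + rng.normal(size=30) * 0.5
        m = regression_metrics(y, yhat)
        assert m.pearson_r == pytest.approx(np.corrcoef(y, yhat)[0, 1])
        assert m.r_as_printed <= 1.0
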