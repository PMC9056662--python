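"""Regression oracles (OLS equivalence, grid-search brute force, coefficient
recovery) and the R2/RMSE/RPD metric conventions."""

import numpy as np
import pytest

from brixmap import (
    EvalMetrics,
    SpectraTable,
    SVRParams,
    evaluate,
    fit_mlr,
    fit_plsr,
    fit_svr,
    grid_search_svr,
    select_plsr_rank,
)
from brixmap.errors import ConfigError, FitError
from brixmap.regress import MLRCalibrator, PLSRCalibrator, SVRCalibrator, r_squared, rmse, rpd


class TestPLSR:
    def test_full_rank_equals_ols(self, linear_table):
        t = linear_table
        model = fit_plsr(t, n_components=t.n_bands)
        A = np.column_stack([np.ones(t.n_samples), t.x])
        ols, *_ = np.linalg.lstsq(A, t.y, rcond=None)
        yhat_ols = A @ ols
        assert np.allclose(model.predict(t.x), yhat_ols, atol=1e-8)
        assert np.allclose(model.predict(t.x), t.y, atol=1e-8)  # noiseless

    def test_single_component_one_band_is_simple_regression(self, rng):
        x = rng.normal(size=(30, 1))
        y = 3.0 + 2.0 * x[:, 0] + 0.1 * rng.normal(size=30)
        t = SpectraTable(x=x, wavelengths=np.array([500.0]), y=y)
        model = fit_plsr(t, n_components=1)
        slope, intercept = np.polyfit(x[:, 0], y, 1)
        assert model.coef_[0] == pytest.approx(slope, abs=1e-8)
        assert model.intercept_ == pytest.approx(intercept, abs=1e-8)

    def test_score_vectors_mutually_orthogonal(self, small_table):
        t = small_table
        model = fit_plsr(t, n_components=6)
        T = model.x_scores_
        G = T.T @ T
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-8

    def test_rank_selection_returns_valid_rank(self, small_table):
        rank = select_plsr_rank(small_table, max_rank=8)
        assert 1 <= rank <= 8

    def test_zero_variance_response_rejected(self, rng):
        t = SpectraTable(
            x=rng.normal(size=(20, 5)), wavelengths=np.arange(5.0) + 400,
            y=np.ones(20),
        )
        with pytest.raises(FitError):
            fit_plsr(t, n_components=2)


class TestSVR:
    def test_duplicated_point_predicts_identically(self, rng):
        x = rng.normal(size=(25, 4))
        x[10] = x[3]
        y = x @ np.ones(4) + 0.05 * rng.normal(size=25)
        y[10] = y[3]
        t = SpectraTable(x=x, wavelengths=np.arange(4.0) + 400, y=y)
        model = fit_svr(t, SVRParams(10.0, 0.1, 0.5))
        preds = model.predict(x[[3, 10]])
        assert preds[0] == pytest.approx(preds[1], abs=1e-12)

    def test_epsilon_tube_on_noiseless_linear_data(self, rng):
        x = np.linspace(-1, 1, 40)[:, None]
        y = 2.0 * x[:, 0] + 1.0
        t = SpectraTable(x=x, wavelengths=np.array([500.0]), y=y)
        eps = 0.01
        model = fit_svr(t, SVRParams(C=1e4, epsilon=eps, gamma=1.0))
        # at the dual optimum residuals live inside the epsilon tube (up to
        # solver tolerance), so the training RMSE cannot exceed epsilon
        train_rmse = np.sqrt(np.mean((model.predict(x) - y) ** 2))
        assert train_rmse < eps + 1e-6

    def test_grid_search_matches_exhaustive_oracle(self, rng):
        x = rng.normal(size=(40, 3))
        y = x @ np.array([1.0, -2.0, 0.5]) + 0.1 * rng.normal(size=40)
        t = SpectraTable(x=x, wavelengths=np.arange(3.0) + 400, y=y)
        C_grid, eps_grid, g_grid = (1.0, 100.0), (0.05, 0.2), (0.1, 1.0)
        got = grid_search_svr(t, C_grid, eps_grid, g_grid, n_folds=5, seed=3)

        # independent oracle: explicit evaluation of all 8 cells
        from sklearn.model_selection import KFold

        folds = list(KFold(5, shuffle=True, random_state=3).split(x))
        best = (np.inf, None)
        for C in C_grid:
            for eps in eps_grid:
                for g in g_grid:
                    sse, n_tot = 0.0, 0
                    for tr, te in folds:
                        m = SVRCalibrator(C, eps, g).fit(x[tr], y[tr])
                        r = m.predict(x[te]) - y[te]
                        sse += float(r @ r)
                        n_tot += te.size
                    score = np.sqrt(sse / n_tot)
                    if score < best[0]:
                        best = (score, (C, eps, g))
        assert (got.C, got.epsilon, got.gamma) == best[1]

    def test_non_positive_grid_rejected(self, linear_table):
        with pytest.raises(ConfigError):
            grid_search_svr(linear_table, C_grid=(0.0, 1.0))


class TestMLR:
    def test_exact_coefficient_recovery_on_noiseless_data(self, rng):
        x = rng.normal(size=(30, 4))
        coef = np.array([1.5, -2.0, 0.7, 3.1])
        y = 0.8 + x @ coef  # zero regression deviation
        t = SpectraTable(x=x, wavelengths=np.arange(4.0) + 400, y=y)
        model = fit_mlr(t)
        assert model.intercept_ == pytest.approx(0.8, abs=1e-8)
        assert np.allclose(model.coef_, coef, atol=1e-8)

    def test_duplicated_band_raises_rank_error(self, rng):
        x = rng.normal(size=(30, 4))
        x[:, 3] = x[:, 0]
        y = x[:, 0] + rng.normal(size=30)
        t = SpectraTable(x=x, wavelengths=np.arange(4.0) + 400, y=y)
        with pytest.raises(FitError, match="collinear"):
            fit_mlr(t)

    def test_backward_elimination_keeps_informative_bands(self):
        kept_all = 0
        trials = 40
        for seed in range(trials):
            rng = np.random.default_rng(3000 + seed)
            x = rng.normal(size=(80, 10))
            coef = np.zeros(10)
            coef[:5] = (2.0, -1.5, 1.0, 2.5, -2.0)  # 5 informative + 5 noise
            y = x @ coef + 0.3 * rng.normal(size=80)
            t = SpectraTable(x=x, wavelengths=np.arange(10.0) + 400, y=y)
            model = fit_mlr(t, alpha=0.05, eliminate=True)
            if set(range(5)) <= set(model.kept_.tolist()):
                kept_all += 1
        assert kept_all >= int(0.9 * trials)

    def test_more_bands_than_samples_rejected(self, rng):
        t = SpectraTable(
            x=rng.normal(size=(5, 8)), wavelengths=np.arange(8.0) + 400,
            y=rng.normal(size=5),
        )
        with pytest.raises(ConfigError):
            fit_mlr(t)


class TestMetrics:
    @pytest.mark.parametrize(
        "sd,rmse_val,expected",
        [
            (0.7560, 0.3687, 2.05),  # prediction-set SD vs RMSEP
            (0.6669, 0.3146, 2.12),  # calibration-set SD vs RMSEC
            (0.7758, 0.3224, 2.41),  # best-pretreatment calibration block
        ],
    )
    def test_rpd_is_reference_sd_over_rmse(self, sd, rmse_val, expected):
        assert round(sd / rmse_val, 2) == expected

    def test_rpd_function_uses_n_minus_1_sd(self, rng):
        y = rng.normal(10, 1, 50)
        assert rpd(y, 0.5) == pytest.approx(np.std(y, ddof=1) / 0.5)

    def test_perfect_predictions_give_inf_rpd_with_warning(self, rng):
        y = rng.normal(10, 1, 30)
        assert r_squared(y, y) == 1.0
        assert rmse(y, y) == 0.0
        with pytest.warns(UserWarning, match="perfect"):
            assert rpd(y, 0.0) == np.inf

    def test_evaluate_same_set_gives_identical_blocks(self, small_table):
        model = fit_plsr(small_table, n_components=3)
        m = evaluate(model, small_table, small_table)
        assert m.r2_cal == m.r2_pred
        assert m.rmsec == m.rmsep
        assert m.rpd_cal == m.rpd_pred

    def test_rounding_convention(self):
        m = EvalMetrics(0.82274, 0.32481, 2.3912, 0.77132, 0.36873, 2.0503)
        r = m.rounded()
        assert r == {
            "r2_cal": 0.8227, "rmsec": 0.3248, "rpd_cal": 2.39,
            "r2_pred": 0.7713, "rmsep": 0.3687, "rpd_pred": 2.05,
        }


def test_plsr_mlr_ols_agree_at_full_rank(rng):
    # three routes to the same least-squares fit on a full-rank design
    x = rng.normal(size=(50, 6))
    y = x @ np.arange(1.0, 7.0) + 0.2 * rng.normal(size=50)
    t = SpectraTable(x=x, wavelengths=np.arange(6.0) + 400, y=y)
    plsr = fit_plsr(t, n_components=6)
    mlr = fit_mlr(t)
    A = np.column_stack([np.ones(50), x])
    ols, *_ = np.linalg.lstsq(A, y, rcond=None)
    yhat = A @ ols
    assert np.allclose(plsr.predict(x), yhat, atol=1e-6)
    assert np.allclose(mlr.predict(x), yhat, atol=1e-6)
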