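"""Calibration models and the R2 / RMSE / RPD evaluation suite.

Three model families are supported, matching common NIR calibration
practice:

* **PLSR** — partial least squares regression on mean-centered data
  (NIPALS; successive weight vectors maximize covariance with the residual
  response).  The rank ("PCs") can be chosen by 10-fold RMSECV.
* **SVR** — epsilon-insensitive support vector regression with a
  radial-basis kernel, inputs standardized per band on the calibration set;
  the (C, epsilon, gamma) triple is chosen by exhaustive grid search over
  mean 10-fold CV RMSE.
* **MLR** — ordinary least squares on the selected wavelengths,
  Y = a0 + a1 X1 + ... + ai Xi + e, with per-coefficient t-test p-values
  and optional backward elimination at a significance level alpha.

Metrics follow the chemometrics conventions: RMSE is the root mean squared
error, R2 = 1 - SSE/SST about the evaluated set's own mean, and
RPD = SD(reference y of that set) / RMSE with the n-1 SD divisor.  An RPD
above ~2 conventionally marks a usable calibration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import KFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR
from sklearn.utils.validation import check_X_y, check_is_fitted
import statsmodels.api as sm

from .cube_io import SpectraTable
from .errors import ConfigError, FitError
from .wavesel import cv_rmse_pls

__all__ = [
    "PLSRCalibrator",
    "SVRCalibrator",
    "MLRCalibrator",
    "SVRParams",
    "EvalMetrics",
    "fit_plsr",
    "select_plsr_rank",
    "fit_svr",
    "grid_search_svr",
    "fit_mlr",
    "evaluate",
    "rmse",
    "r_squared",
    "rpd",
]


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def rmse(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    return float(np.sqrt(np.mean((y_true - y_pred) ** 2)))


def r_squared(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """R2 = 1 - SSE/SST, SST about the evaluated set's own mean."""
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    sst = float(np.sum((y_true - y_true.mean()) ** 2))
    if sst == 0:
        raise FitError("reference values have zero variance; R2 undefined")
    sse = float(np.sum((y_true - y_pred) ** 2))
    return 1.0 - sse / sst


def rpd(y_true: np.ndarray, rmse_value: float) -> float:
    """Residual predictive deviation: SD(y, n-1 divisor) / RMSE."""
    y_true = np.asarray(y_true, dtype=float).ravel()
    sd = float(np.std(y_true, ddof=1))
    if sd == 0:
        raise FitError("reference values have zero variance; RPD undefined")
    if rmse_value == 0:
        warnings.warn("perfect predictions: RPD reported as inf", stacklevel=2)
        return float("inf")
    return sd / rmse_value


def rpd_from_sd(sd: float, rmse_value: float, decimals: int = 2) -> float:
    """RPD from an already-computed reference SD and RMSE (report rounding).

    Useful for cross-checking published results tables, where only SD and
    RMSE are printed.
    """
    if sd <= 0 or rmse_value <= 0:
        raise FitError("RPD needs positive SD and RMSE")
    return round(sd / rmse_value, decimals)


@dataclass
class EvalMetrics:
    """Calibration/prediction metric blocks (the usual results-table row)."""

    r2_cal: float
    rmsec: float
    rpd_cal: float
    r2_pred: float
    rmsep: float
    rpd_pred: float

    def rounded(self) -> dict:
        """Report rounding: 4 decimals for R2/RMSE, 2 for RPD."""
        return {
            "r2_cal": round(self.r2_cal, 4),
            "rmsec": round(self.rmsec, 4),
            "rpd_cal": round(self.rpd_cal, 2),
            "r2_pred": round(self.r2_pred, 4),
            "rmsep": round(self.rmsep, 4),
            "rpd_pred": round(self.rpd_pred, 2),
        }


def evaluate(model, cal: SpectraTable, pred: SpectraTable) -> EvalMetrics:
    """Evaluate a fitted model on calibration and prediction sets."""
    if cal.y is None or pred.y is None:
        raise ConfigError("both sets need reference values")
    yc_hat = np.asarray(model.predict(cal.x)).ravel()
    yp_hat = np.asarray(model.predict(pred.x)).ravel()
    rmsec = rmse(cal.y, yc_hat)
    rmsep = rmse(pred.y, yp_hat)
    return EvalMetrics(
        r2_cal=r_squared(cal.y, yc_hat),
        rmsec=rmsec,
        rpd_cal=rpd(cal.y, rmsec),
        r2_pred=r_squared(pred.y, yp_hat),
        rmsep=rmsep,
        rpd_pred=rpd(pred.y, rmsep),
    )


# ---------------------------------------------------------------------------
# PLSR
# ---------------------------------------------------------------------------


class PLSRCalibrator(RegressorMixin, BaseEstimator):
    """PLS regression (NIPALS, mean-centered, unscaled).

    Attributes after fit: ``pls_`` (the underlying decomposition),
    ``x_scores_`` (mutually orthogonal score vectors), ``coef_`` and
    ``intercept_`` of the equivalent linear predictor.
    """

    def __init__(self, n_components: int = 10):
        self.n_components = n_components

    def fit(self, X, y):
        X, y = check_X_y(X, y, y_numeric=True)
        if np.std(y) == 0:
            raise FitError("zero-variance response")
        limit = min(X.shape[0] - 1, X.shape[1])
        if not 1 <= self.n_components <= limit:
            raise ConfigError(
                f"n_components={self.n_components} outside [1, {limit}]"
            )
        self.pls_ = PLSRegression(n_components=self.n_components, scale=False)
        self.pls_.fit(X, y)
        self.x_scores_ = self.pls_.x_scores_
        self.coef_ = np.asarray(self.pls_.coef_).reshape(-1)
        # the underlying decomposition centers X internally; fold the
        # centering into an explicit linear form y = x @ coef + intercept
        y_mean = float(np.asarray(self.pls_.intercept_).ravel()[0])
        self.intercept_ = y_mean - float(self.pls_._x_mean @ self.coef_)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "pls_")
        return np.asarray(X, dtype=float) @ self.coef_ + self.intercept_

    def get_state(self) -> dict:
        check_is_fitted(self, "pls_")
        return {
            "kind": "plsr",
            "n_components": int(self.n_components),
            "coef": self.coef_.tolist(),
            "intercept": self.intercept_,
        }

    @classmethod
    def from_state(cls, state: dict) -> "PLSRCalibrator":
        obj = cls(n_components=state["n_components"])
        obj.coef_ = np.asarray(state["coef"], dtype=float)
        obj.intercept_ = float(state["intercept"])
        obj.pls_ = None  # linear predictor is sufficient for prediction
        obj.n_features_in_ = obj.coef_.size
        return obj

    # from_state leaves pls_ = None; predict only needs coef/intercept
    def __sklearn_is_fitted__(self):
        return hasattr(self, "coef_")


def select_plsr_rank(
    cal: SpectraTable | None = None,
    max_rank: int = 20,
    n_folds: int = 10,
    X=None,
    y=None,
) -> int:
    """Rank ("PCs") minimizing 10-fold RMSECV, ties toward fewer components."""
    if cal is not None:
        X, y = cal.x, cal.y
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    limit = min(max_rank, X.shape[1], X.shape[0] - max(2, X.shape[0] // n_folds) - 1)
    limit = max(1, limit)
    scores = [cv_rmse_pls(X, y, ncomp, n_folds) for ncomp in range(1, limit + 1)]
    return int(np.argmin(scores)) + 1


def fit_plsr(cal: SpectraTable, n_components: int) -> PLSRCalibrator:
    return PLSRCalibrator(n_components=n_components).fit(cal.x, cal.y)


# ---------------------------------------------------------------------------
# SVR
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SVRParams:
    """(C, epsilon, gamma) for the radial-basis epsilon-SVR."""

    C: float = 100.0
    epsilon: float = 0.1
    gamma: float = 0.077

    def validate(self) -> None:
        for name in ("C", "epsilon", "gamma"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"SVR parameter {name} must be strictly positive")


#: Default search grids; bracket the optima typically reported for
#: produce-SSC calibrations (C ~ 100, epsilon ~ 0.1, gamma ~ 0.03-0.08).
DEFAULT_C_GRID = (1.0, 10.0, 100.0, 1000.0)
DEFAULT_EPS_GRID = (0.01, 0.1, 0.5)
DEFAULT_GAMMA_GRID = tuple(np.logspace(-3, 0, 20))


class SVRCalibrator(RegressorMixin, BaseEstimator):
    """Epsilon-SVR with RBF kernel on per-band standardized inputs.

    Standardization (zero mean, unit variance, fitted on the calibration
    set) makes the radial-basis width gamma comparable across bands.
    """

    def __init__(self, C: float = 100.0, epsilon: float = 0.1, gamma: float = 0.077):
        self.C = C
        self.epsilon = epsilon
        self.gamma = gamma

    def fit(self, X, y):
        X, y = check_X_y(X, y, y_numeric=True)
        SVRParams(self.C, self.epsilon, self.gamma).validate()
        self.scaler_ = StandardScaler().fit(X)
        self.svr_ = SVR(kernel="rbf", C=self.C, epsilon=self.epsilon, gamma=self.gamma)
        self.svr_.fit(self.scaler_.transform(X), y)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "svr_")
        Xs = (np.asarray(X, dtype=float) - self.scaler_mean_) / self.scaler_scale_
        if self.svr_ is not None:
            return self.svr_.predict(Xs)
        # restored from serialized state: evaluate the RBF expansion directly
        sq = (
            np.sum(Xs**2, axis=1)[:, None]
            - 2.0 * Xs @ self._sv_.T
            + np.sum(self._sv_**2, axis=1)[None, :]
        )
        K = np.exp(-self.gamma * sq)
        return K @ self._dual_ + self._b_

    @property
    def scaler_mean_(self):
        return self.scaler_.mean_ if getattr(self, "scaler_", None) is not None else self._mu_

    @property
    def scaler_scale_(self):
        return self.scaler_.scale_ if getattr(self, "scaler_", None) is not None else self._sig_

    def get_state(self) -> dict:
        check_is_fitted(self, "svr_")
        return {
            "kind": "svr",
            "C": self.C,
            "epsilon": self.epsilon,
            "gamma": self.gamma,
            "mean": self.scaler_.mean_.tolist(),
            "scale": self.scaler_.scale_.tolist(),
            "support_vectors": self.svr_.support_vectors_.tolist(),
            "dual_coef": self.svr_.dual_coef_.ravel().tolist(),
            "intercept": float(self.svr_.intercept_[0]),
        }

    @classmethod
    def from_state(cls, state: dict) -> "SVRCalibrator":
        obj = cls(C=state["C"], epsilon=state["epsilon"], gamma=state["gamma"])
        obj.scaler_ = None
        obj.svr_ = None
        obj._mu_ = np.asarray(state["mean"], dtype=float)
        obj._sig_ = np.asarray(state["scale"], dtype=float)
        obj._sv_ = np.asarray(state["support_vectors"], dtype=float)
        obj._dual_ = np.asarray(state["dual_coef"], dtype=float)
        obj._b_ = float(state["intercept"])
        obj.n_features_in_ = obj._mu_.size
        return obj

    def __sklearn_is_fitted__(self):
        return getattr(self, "svr_", None) is not None or hasattr(self, "_sv_")


def fit_svr(cal: SpectraTable, params: SVRParams) -> SVRCalibrator:
    params.validate()
    return SVRCalibrator(params.C, params.epsilon, params.gamma).fit(cal.x, cal.y)


def grid_search_svr(
    cal: SpectraTable | None = None,
    C_grid=DEFAULT_C_GRID,
    eps_grid=DEFAULT_EPS_GRID,
    gamma_grid=DEFAULT_GAMMA_GRID,
    n_folds: int = 10,
    seed: int | None = 0,
    X=None,
    y=None,
) -> SVRParams:
    """Exhaustive grid search minimizing mean k-fold CV RMSE.

    The grid is traversed in row-major (C, epsilon, gamma) order and ties
    keep the first minimizer, so the result is independent of how the caller
    enumerates an equivalent grid.
    """
    if cal is not None:
        X, y = cal.x, cal.y
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    for name, grid in (("C", C_grid), ("epsilon", eps_grid), ("gamma", gamma_grid)):
        if len(grid) == 0:
            raise ConfigError(f"{name} grid is empty")
        if any(v <= 0 for v in grid):
            raise ConfigError(f"{name} grid contains non-positive values")
    n_folds = min(n_folds, X.shape[0])
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = list(kf.split(X))

    best = None
    best_score = np.inf
    for C in C_grid:
        for eps in eps_grid:
            for gamma in gamma_grid:
                sse, n_total = 0.0, 0
                for tr, te in folds:
                    model = SVRCalibrator(C, eps, gamma).fit(X[tr], y[tr])
                    resid = model.predict(X[te]) - y[te]
                    sse += float(resid @ resid)
                    n_total += te.size
                score = float(np.sqrt(sse / n_total))
                if score < best_score:
                    best_score = score
                    best = SVRParams(float(C), float(eps), float(gamma))
    return best


# ---------------------------------------------------------------------------
# MLR
# ---------------------------------------------------------------------------


class MLRCalibrator(RegressorMixin, BaseEstimator):
    """Ordinary least squares on selected wavelengths with t-test p-values.

    With ``eliminate=True``, backward elimination drops the coefficient with
    the largest p-value above ``alpha`` until all survivors are significant
    (the intercept is never dropped).

    Attributes after fit: ``intercept_``, ``coef_``, ``pvalues_`` (per
    retained coefficient), ``kept_`` (positions of retained input columns).
    """

    def __init__(self, alpha: float = 0.05, eliminate: bool = False):
        self.alpha = alpha
        self.eliminate = eliminate

    def fit(self, X, y):
        X, y = check_X_y(X, y, y_numeric=True)
        n, p = X.shape
        if p >= n:
            raise ConfigError(f"need fewer wavelengths ({p}) than samples ({n})")
        A = sm.add_constant(X, has_constant="add")
        if np.linalg.matrix_rank(A) < A.shape[1]:
            # identify a redundant column via QR pivots on the band block
            r = np.abs(np.diag(np.linalg.qr(A, mode="r")))
            bad = np.flatnonzero(r < r.max() * 1e-10)
            raise FitError(
                f"rank-deficient design; collinear column(s) near {bad.tolist()}"
            )
        kept = np.arange(p)
        while True:
            res = sm.OLS(y, sm.add_constant(X[:, kept], has_constant="add")).fit()
            pvals = res.pvalues[1:]
            if not self.eliminate or kept.size == 1:
                break
            worst = int(np.argmax(pvals))
            if pvals[worst] <= self.alpha:
                break
            kept = np.delete(kept, worst)
        self.results_ = res
        self.kept_ = kept
        self.intercept_ = float(res.params[0])
        coef = np.zeros(p)
        coef[kept] = res.params[1:]
        self.coef_ = coef
        self.pvalues_ = np.asarray(res.pvalues[1:])
        self.n_features_in_ = p
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        return np.asarray(X, dtype=float) @ self.coef_ + self.intercept_

    def get_state(self) -> dict:
        check_is_fitted(self, "coef_")
        return {
            "kind": "mlr",
            "alpha": self.alpha,
            "coef": self.coef_.tolist(),
            "intercept": self.intercept_,
            "kept": [int(i) for i in self.kept_],
        }

    @classmethod
    def from_state(cls, state: dict) -> "MLRCalibrator":
        obj = cls(alpha=state["alpha"])
        obj.coef_ = np.asarray(state["coef"], dtype=float)
        obj.intercept_ = float(state["intercept"])
        obj.kept_ = np.asarray(state["kept"], dtype=int)
        obj.n_features_in_ = obj.coef_.size
        return obj

    def __sklearn_is_fitted__(self):
        return hasattr(self, "coef_")


def fit_mlr(cal: SpectraTable, alpha: float = 0.05, eliminate: bool = False) -> MLRCalibrator:
    return MLRCalibrator(alpha=alpha, eliminate=eliminate).fit(cal.x, cal.y)


MODEL_STATE_LOADERS = {
    "plsr": PLSRCalibrator.from_state,
    "svr": SVRCalibrator.from_state,
    "mlr": MLRCalibrator.from_state,
}


def model_from_state(state: dict):
    return MODEL_STATE_LOADERS[state["kind"]](state)
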