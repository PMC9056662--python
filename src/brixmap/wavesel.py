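"""Characteristic-wavelength selection: SPA and CARS.

Full-resolution Vis-NIR spectra (256 bands here) are heavily collinear;
both selectors search for a small informative subset.

**SPA** (successive projections algorithm) is deterministic forward
selection that minimizes collinearity: starting from a candidate band, each
iteration projects every unselected band's column vector onto the
orthogonal complement of the span of the selected ones and appends the
column with the largest residual norm.  Chains are grown from every start
band for every length in ``[m_min, m_max]`` and scored by 10-fold
cross-validated RMSE of a multiple linear regression (RMSECV); the
globally best chain wins.

**CARS** (competitive adaptive reweighted sampling) runs N Monte Carlo
iterations.  Each iteration fits a PLS model on a random subsample of the
calibration samples restricted to the currently retained bands; the number
of bands to keep follows an exponentially decreasing function (EDF) with
endpoints r_1 = 1 and r_N = 2/p; which bands survive is decided
competitively by |PLS regression coefficient| — the top-weighted band is
always kept (enforced reduction) and the rest are drawn by weighted
sampling without replacement (adaptive reweighted sampling).  Every
iteration's retained subset is scored by 10-fold PLS RMSECV on the full
calibration set and the minimizer is returned.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import KFold
from sklearn.utils.validation import check_X_y

from .cube_io import SpectraTable
from .errors import ConfigError, SelectionError

logger = logging.getLogger(__name__)

__all__ = [
    "SelectionResult",
    "SPASelector",
    "CARSSelector",
    "spa_select",
    "cars_select",
    "report_selection",
    "edf_ratio",
    "cv_rmse_mlr",
    "cv_rmse_pls",
]


@dataclass
class SelectionResult:
    """Outcome of a wavelength-selection run."""

    method: str
    selected: list[int]
    selected_nm: list[float]
    score_trace: list[tuple]
    settings: dict = field(default_factory=dict)

    @property
    def best_rmsecv(self) -> float:
        return min(s[-1] for s in self.score_trace)

    def to_json(self, path=None) -> str:
        payload = {
            "method": self.method,
            "selected": [int(i) for i in self.selected],
            "selected_nm": [float(w) for w in self.selected_nm],
            "score_trace": [list(t) for t in self.score_trace],
            "settings": self.settings,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


# ---------------------------------------------------------------------------
# Cross-validation scorers
# ---------------------------------------------------------------------------


def cv_rmse_mlr(X: np.ndarray, y: np.ndarray, n_folds: int = 10) -> float:
    """10-fold RMSECV of ordinary least squares with intercept.

    Folds are contiguous and deterministic (no shuffling), so SPA is fully
    reproducible without a seed.
    """
    n = X.shape[0]
    n_folds = min(n_folds, n)
    kf = KFold(n_splits=n_folds, shuffle=False)
    A = np.column_stack([np.ones(n), X])
    sse = 0.0
    for tr, te in kf.split(A):
        coef, *_ = np.linalg.lstsq(A[tr], y[tr], rcond=None)
        resid = A[te] @ coef - y[te]
        sse += float(resid @ resid)
    return float(np.sqrt(sse / n))


def cv_rmse_pls(
    X: np.ndarray, y: np.ndarray, n_components: int, n_folds: int = 10
) -> float:
    """10-fold RMSECV of a PLS regression (components clamped per fold)."""
    n = X.shape[0]
    n_folds = min(n_folds, n)
    kf = KFold(n_splits=n_folds, shuffle=False)
    sse = 0.0
    for tr, te in kf.split(X):
        ncomp = max(1, min(n_components, X.shape[1], tr.size - 1))
        pls = PLSRegression(n_components=ncomp, scale=False)
        pls.fit(X[tr], y[tr])
        resid = pls.predict(X[te]).ravel() - y[te]
        sse += float(resid @ resid)
    return float(np.sqrt(sse / n))


# ---------------------------------------------------------------------------
# SPA
# ---------------------------------------------------------------------------


def spa_chain(X: np.ndarray, start: int, m_max: int) -> list[int]:
    """Grow one SPA chain from ``start`` up to length ``m_max``.

    Iteratively deflates every column by its projection on the most recently
    selected column and appends the column of maximal residual norm
    (ties -> lowest index).
    """
    P = np.asarray(X, dtype=float).copy()
    chain = [start]
    selected = np.zeros(X.shape[1], dtype=bool)
    selected[start] = True
    for _ in range(m_max - 1):
        v = P[:, chain[-1]]
        nv = float(v @ v)
        if nv == 0:
            break
        P = P - np.outer(v, (v @ P) / nv)
        P[:, selected] = 0.0
        norms = np.einsum("ij,ij->j", P, P)
        if norms.max() <= 1e-24:
            break
        nxt = int(np.argmax(norms))
        chain.append(nxt)
        selected[nxt] = True
    return chain


class SPASelector(BaseEstimator):
    """Successive-projections wavelength selector scored by MLR RMSECV.

    Parameters
    ----------
    m_min, m_max : chain lengths evaluated (inclusive).
    n_folds : folds for the MLR cross-validation score.
    max_starts : optional cap on the number of start bands; when set, starts
        are ranked by |correlation with y| and the top ``max_starts`` kept
        (all bands by default).
    """

    def __init__(self, m_min: int = 2, m_max: int = 25, n_folds: int = 10,
                 max_starts: int | None = None):
        self.m_min = m_min
        self.m_max = m_max
        self.n_folds = n_folds
        self.max_starts = max_starts

    def fit(self, X, y):
        X, y = check_X_y(X, y, y_numeric=True)
        n, p = X.shape
        if not 1 <= self.m_min <= self.m_max:
            raise ConfigError("need 1 <= m_min <= m_max")
        if self.m_max >= min(p, n):
            raise ConfigError(
                f"m_max={self.m_max} must be < min(bands={p}, samples={n})"
            )
        starts = np.arange(p)
        if self.max_starts is not None and self.max_starts < p:
            Xc = X - X.mean(axis=0)
            yc = y - y.mean()
            sd = Xc.std(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                corr = np.abs(Xc.T @ yc) / np.where(sd > 0, sd, np.inf)
            starts = np.sort(np.argsort(-corr, kind="stable")[: self.max_starts])

        best_score = np.inf
        best_chain: list[int] | None = None
        trace: list[tuple] = []
        n_skipped = 0
        for k in starts:
            if float(X[:, k] @ X[:, k]) == 0:
                n_skipped += 1
                logger.info("SPA: start band %d has zero norm, skipped", k)
                continue
            chain = spa_chain(X, int(k), self.m_max)
            for m in range(self.m_min, min(self.m_max, len(chain)) + 1):
                score = cv_rmse_mlr(X[:, chain[:m]], y, self.n_folds)
                trace.append((int(k), m, score))
                if score < best_score:
                    best_score = score
                    best_chain = chain[:m]
        if best_chain is None:
            raise SelectionError("every SPA start band was degenerate")
        self.selected_idx_ = np.array(best_chain)
        self.support_ = np.zeros(p, dtype=bool)
        self.support_[self.selected_idx_] = True
        self.best_rmsecv_ = best_score
        self.score_trace_ = trace
        self.n_features_in_ = p
        return self

    def get_support(self, indices: bool = False):
        return self.selected_idx_.copy() if indices else self.support_.copy()

    def transform(self, X):
        return np.asarray(X)[:, self.selected_idx_]

    def to_result(self, wavelengths: np.ndarray) -> SelectionResult:
        return SelectionResult(
            method="spa",
            selected=sorted(int(i) for i in self.selected_idx_),
            selected_nm=[float(wavelengths[i]) for i in sorted(self.selected_idx_)],
            score_trace=self.score_trace_,
            settings={
                "m_min": self.m_min,
                "m_max": self.m_max,
                "n_folds": self.n_folds,
                "max_starts": self.max_starts,
            },
        )


# ---------------------------------------------------------------------------
# CARS
# ---------------------------------------------------------------------------


def edf_ratio(i: int, n_runs: int, p: int) -> float:
    """Exponentially decreasing retain-ratio with r_1 = 1 and r_N = 2/p."""
    if n_runs < 2:
        raise ConfigError("CARS needs n_runs >= 2")
    a = (p / 2.0) ** (1.0 / (n_runs - 1))
    k = np.log(p / 2.0) / (n_runs - 1)
    return float(a * np.exp(-k * i))


def _weighted_sample_without_replacement(
    rng: np.random.Generator, items: np.ndarray, weights: np.ndarray, k: int
) -> np.ndarray:
    """Efraimidis-Spirakis weighted reservoir: top-k of u^(1/w) keys."""
    w = np.clip(weights, 1e-12, None)
    keys = rng.random(items.size) ** (1.0 / w)
    return items[np.argsort(-keys, kind="stable")[:k]]


class CARSSelector(BaseEstimator):
    """Competitive adaptive reweighted sampling wavelength selector.

    Parameters
    ----------
    n_runs : Monte Carlo iterations N of the EDF schedule.
    cal_subsample : fraction of calibration samples drawn (without
        replacement) to fit each iteration's PLS model.
    n_folds : folds for the PLS RMSECV that scores every retained subset.
    max_components : PLS rank cap; the effective rank is
        min(cap, retained bands, subsample size - 1).
    random_state : seed; fixed seed reproduces the run exactly.
    """

    def __init__(self, n_runs: int = 50, cal_subsample: float = 0.8,
                 n_folds: int = 10, max_components: int = 10,
                 random_state: int | None = 0):
        self.n_runs = n_runs
        self.cal_subsample = cal_subsample
        self.n_folds = n_folds
        self.max_components = max_components
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y, y_numeric=True)
        n, p = X.shape
        if self.n_runs < 2:
            raise ConfigError("CARS needs n_runs >= 2")
        if not 0 < self.cal_subsample <= 1:
            raise ConfigError("cal_subsample must be in (0, 1]")
        rng = np.random.default_rng(self.random_state)
        n_sub = max(2, int(round(self.cal_subsample * n)))

        retained = np.arange(p)
        trace: list[tuple] = []
        subsets: list[np.ndarray] = []
        retained_counts: list[int] = []
        stopped_early = False
        for i in range(1, self.n_runs + 1):
            if retained.size < 2:
                stopped_early = True
                warnings.warn(
                    f"CARS retained <2 bands at run {i}; stopping early with "
                    "best subset so far",
                    stacklevel=2,
                )
                break
            sub = rng.choice(n, size=n_sub, replace=False)
            ncomp = max(1, min(self.max_components, retained.size, n_sub - 1))
            pls = PLSRegression(n_components=ncomp, scale=False)
            pls.fit(X[np.ix_(sub, retained)], y[sub])
            w = np.abs(np.asarray(pls.coef_).reshape(-1))

            k_i = max(2, int(round(edf_ratio(i, self.n_runs, p) * p)))
            if k_i < retained.size:
                top = int(np.argmax(w))  # enforced: best band always survives
                rest = np.delete(np.arange(retained.size), top)
                picked = _weighted_sample_without_replacement(
                    rng, rest, w[rest], k_i - 1
                )
                keep_local = np.sort(np.concatenate(([top], picked)))
                retained = retained[keep_local]

            score = cv_rmse_pls(
                X[:, retained], y,
                n_components=min(self.max_components, retained.size),
                n_folds=self.n_folds,
            )
            subsets.append(retained.copy())
            retained_counts.append(retained.size)
            trace.append((i, retained.size, score))

        if not subsets:
            raise SelectionError("CARS produced no candidate subsets")
        best_run = int(np.argmin([t[-1] for t in trace]))
        self.selected_idx_ = np.sort(subsets[best_run])
        self.support_ = np.zeros(p, dtype=bool)
        self.support_[self.selected_idx_] = True
        self.best_rmsecv_ = trace[best_run][-1]
        self.score_trace_ = trace
        self.retained_counts_ = retained_counts
        self.stopped_early_ = stopped_early
        self.n_features_in_ = p
        return self

    def get_support(self, indices: bool = False):
        return self.selected_idx_.copy() if indices else self.support_.copy()

    def transform(self, X):
        return np.asarray(X)[:, self.selected_idx_]

    def to_result(self, wavelengths: np.ndarray) -> SelectionResult:
        return SelectionResult(
            method="cars",
            selected=[int(i) for i in self.selected_idx_],
            selected_nm=[float(wavelengths[i]) for i in self.selected_idx_],
            score_trace=self.score_trace_,
            settings={
                "n_runs": self.n_runs,
                "cal_subsample": self.cal_subsample,
                "n_folds": self.n_folds,
                "max_components": self.max_components,
                "seed": self.random_state,
            },
        )


# ---------------------------------------------------------------------------
# Functional wrappers and reporting
# ---------------------------------------------------------------------------


def spa_select(
    cal: SpectraTable, m_min: int = 2, m_max: int = 25, n_folds: int = 10,
    max_starts: int | None = None,
) -> SelectionResult:
    if cal.y is None:
        raise ConfigError("SPA requires reference values (cal.y)")
    sel = SPASelector(m_min=m_min, m_max=m_max, n_folds=n_folds, max_starts=max_starts)
    sel.fit(cal.x, cal.y)
    return sel.to_result(cal.wavelengths)


def cars_select(
    cal: SpectraTable, n_runs: int = 50, cal_subsample: float = 0.8,
    n_folds: int = 10, seed: int | None = 0, max_components: int = 10,
) -> SelectionResult:
    if cal.y is None:
        raise ConfigError("CARS requires reference values (cal.y)")
    sel = CARSSelector(
        n_runs=n_runs, cal_subsample=cal_subsample, n_folds=n_folds,
        max_components=max_components, random_state=seed,
    )
    sel.fit(cal.x, cal.y)
    return sel.to_result(cal.wavelengths)


def selected_percentage(n_selected: int, total_bands: int) -> float:
    """Share of retained bands as a percentage, reported to 2 decimals."""
    return round(100.0 * n_selected / total_bands, 2)


def report_selection(result: SelectionResult, total_bands: int) -> dict:
    """Count, percentage of total bands, and the wavelength list."""
    count = len(result.selected)
    return {
        "method": result.method,
        "count": count,
        "percentage": selected_percentage(count, total_bands),
        "wavelengths_nm": [round(w, 1) for w in result.selected_nm],
    }
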