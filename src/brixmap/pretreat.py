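"""Spectral pretreatments as sklearn-compatible transformers.

Six methods commonly compared in NIR calibration work are provided:

========  ==================================================================
baseline  per-spectrum offset subtraction (row minimum, or a line through
          the two endpoint bands in ``mode='endpoints'``)
detrend   subtract a per-spectrum least-squares polynomial in wavelength
          (order 2 by default)
ma        centered moving-average smoothing, mirror padding
msc       multiplicative scatter correction against the calibration-mean
          reference spectrum
sg        Savitzky-Golay smoothing (optionally a derivative), mirror padding
snv       standard normal variate: per-row standardization
========  ==================================================================

All transforms are row-separable and band-count preserving, so a fitted
transformer can be replayed on single-pixel spectra when building maps.
Only MSC carries fitted state (the reference spectrum); the rest are
stateless but still follow the fit/transform protocol so they can slot
into pipelines.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import savgol_filter
from scipy.ndimage import correlate1d
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .errors import ConfigError, FitError, TransformError

__all__ = [
    "SNV",
    "MSC",
    "Detrend",
    "BaselineOffset",
    "MovingAverage",
    "SavitzkyGolay",
    "IdentityPretreatment",
    "make_pretreatment",
    "PRETREATMENTS",
]


class _SpectralTransformer(TransformerMixin, BaseEstimator):
    """Shared validation; subclasses implement ``_transform_rows``."""

    def fit(self, X, y=None):
        X = check_array(X, ensure_min_features=2)
        self.n_features_in_ = X.shape[1]
        self._fit(X)
        return self

    def _fit(self, X):  # stateless by default
        self.fitted_ = True

    def transform(self, X):
        check_is_fitted(self)
        X = check_array(X, ensure_min_features=2)
        if X.shape[1] != self.n_features_in_:
            raise TransformError(
                f"expected {self.n_features_in_} bands, got {X.shape[1]}"
            )
        return self._transform_rows(np.asarray(X, dtype=float))

    def get_state(self) -> dict:
        """JSON-serializable fitted state (overridden where stateful)."""
        check_is_fitted(self)
        return {"n_features_in": int(self.n_features_in_)}

    def set_state(self, state: dict):
        self.n_features_in_ = int(state["n_features_in"])
        self.fitted_ = True
        return self


class IdentityPretreatment(_SpectralTransformer):
    """No-op pretreatment ('original spectra' condition)."""

    def _transform_rows(self, X):
        return X.copy()


class SNV(_SpectralTransformer):
    """Standard normal variate: (row - mean(row)) / sd(row), sd with n-1.

    Removes per-spectrum multiplicative gain and additive offset; invariant
    to positive affine rescaling of a spectrum.
    """

    def _transform_rows(self, X):
        mu = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, ddof=1, keepdims=True)
        bad = np.flatnonzero(sd.ravel() == 0)
        if bad.size:
            raise TransformError(f"SNV undefined for constant row(s) {bad.tolist()}")
        return (X - mu) / sd


class MSC(_SpectralTransformer):
    """Multiplicative scatter correction.

    ``fit`` stores the calibration-set mean spectrum as the reference; each
    transformed row is regressed on the reference (slope b, intercept a) and
    returned as (row - a) / b.  The calibration reference is always reused at
    prediction time -- the transformer refuses to run unfitted.
    """

    min_slope: float = 1e-12

    def _fit(self, X):
        self.reference_ = X.mean(axis=0)

    def _transform_rows(self, X):
        ref = self.reference_
        ref_c = ref - ref.mean()
        denom = float(ref_c @ ref_c)
        if denom == 0:
            raise TransformError("MSC reference spectrum is constant")
        slope = (X - X.mean(axis=1, keepdims=True)) @ ref_c / denom
        bad = np.flatnonzero(np.abs(slope) < self.min_slope)
        if bad.size:
            raise TransformError(
                f"MSC slope below {self.min_slope:g} for row(s) {bad.tolist()}"
            )
        intercept = X.mean(axis=1) - slope * ref.mean()
        return (X - intercept[:, None]) / slope[:, None]

    def get_state(self):
        state = super().get_state()
        state["reference"] = [float(v) for v in self.reference_]
        return state

    def set_state(self, state):
        super().set_state(state)
        self.reference_ = np.asarray(state["reference"], dtype=float)
        return self


class Detrend(_SpectralTransformer):
    """Subtract a per-row least-squares polynomial in wavelength.

    Order 2 removes curvature-type baseline drift.  The polynomial basis is
    the band index (affinely equivalent to wavelength for an evenly sampled
    axis; for uneven axes pass ``wavelengths``).
    """

    def __init__(self, order: int = 2, wavelengths=None):
        self.order = order
        self.wavelengths = wavelengths

    def _fit(self, X):
        if self.order < 0:
            raise ConfigError("detrend order must be >= 0")
        axis = (
            np.asarray(self.wavelengths, dtype=float)
            if self.wavelengths is not None
            else np.arange(self.n_features_in_, dtype=float)
        )
        if axis.size != self.n_features_in_:
            raise ConfigError("wavelengths length must equal band count")
        # orthonormal polynomial basis -> projection is a single matmul
        V = np.vander((axis - axis.mean()) / (np.ptp(axis) or 1.0), self.order + 1)
        Q, _ = np.linalg.qr(V)
        self._proj_ = Q @ Q.T

    def _transform_rows(self, X):
        return X - X @ self._proj_.T

    def get_state(self):
        state = super().get_state()
        state["order"] = int(self.order)
        state["proj"] = self._proj_.tolist()
        return state

    def set_state(self, state):
        super().set_state(state)
        self.order = int(state["order"])
        self._proj_ = np.asarray(state["proj"], dtype=float)
        return self


class BaselineOffset(_SpectralTransformer):
    """Baseline correction by per-row offset subtraction.

    ``mode='min'`` subtracts the row minimum; ``mode='endpoints'`` subtracts
    the straight line through the first and last band.
    """

    def __init__(self, mode: str = "min"):
        self.mode = mode

    def _fit(self, X):
        if self.mode not in ("min", "endpoints"):
            raise ConfigError(f"baseline mode '{self.mode}' not in ('min','endpoints')")
        super()._fit(X)

    def _transform_rows(self, X):
        if self.mode == "min":
            return X - X.min(axis=1, keepdims=True)
        b = self.n_features_in_
        t = np.arange(b) / (b - 1)
        line = X[:, [0]] * (1 - t)[None, :] + X[:, [-1]] * t[None, :]
        return X - line

    def get_state(self):
        state = super().get_state()
        state["mode"] = self.mode
        return state

    def set_state(self, state):
        super().set_state(state)
        self.mode = state["mode"]
        return self


def _check_window(window: int, n_bands: int, order: int | None = None):
    if window < 3 or window % 2 == 0:
        raise ConfigError(f"window must be odd and >= 3, got {window}")
    if window > n_bands:
        raise ConfigError(f"window {window} exceeds band count {n_bands}")
    if order is not None and order >= window:
        raise ConfigError(f"polynomial order {order} must be < window {window}")


class MovingAverage(_SpectralTransformer):
    """Centered moving-average smoothing with mirror padding (length kept)."""

    def __init__(self, window: int = 9):
        self.window = window

    def _fit(self, X):
        _check_window(self.window, self.n_features_in_)
        super()._fit(X)

    def _transform_rows(self, X):
        kernel = np.full(self.window, 1.0 / self.window)
        return correlate1d(X, kernel, axis=1, mode="mirror")

    def get_state(self):
        state = super().get_state()
        state["window"] = int(self.window)
        return state

    def set_state(self, state):
        super().set_state(state)
        self.window = int(state["window"])
        return self


class SavitzkyGolay(_SpectralTransformer):
    """Savitzky-Golay smoothing / derivative, mirror padding (length kept).

    With derivative 0 and polynomial order p, any polynomial spectrum of
    degree <= p passes through unchanged at interior bands.
    """

    def __init__(self, window: int = 9, order: int = 2, deriv: int = 0):
        self.window = window
        self.order = order
        self.deriv = deriv

    def _fit(self, X):
        _check_window(self.window, self.n_features_in_, self.order)
        if self.deriv > self.order:
            raise ConfigError("derivative order must be <= polynomial order")
        super()._fit(X)

    def _transform_rows(self, X):
        return savgol_filter(
            X, self.window, self.order, deriv=self.deriv, axis=1, mode="mirror"
        )

    def get_state(self):
        state = super().get_state()
        state.update(window=int(self.window), order=int(self.order), deriv=int(self.deriv))
        return state

    def set_state(self, state):
        super().set_state(state)
        self.window = int(state["window"])
        self.order = int(state["order"])
        self.deriv = int(state["deriv"])
        return self


PRETREATMENTS = {
    "none": IdentityPretreatment,
    "original": IdentityPretreatment,
    "baseline": BaselineOffset,
    "detrend": Detrend,
    "ma": MovingAverage,
    "msc": MSC,
    "sg": SavitzkyGolay,
    "snv": SNV,
}


def make_pretreatment(method: str, **params) -> _SpectralTransformer:
    """Factory mapping a method name (as used in config files) to a transformer."""
    try:
        cls = PRETREATMENTS[method.lower()]
    except KeyError:
        raise ConfigError(
            f"unknown pretreatment '{method}'; choose from {sorted(PRETREATMENTS)}"
        ) from None
    return cls(**params)


def pretreatment_to_state(tr: _SpectralTransformer) -> dict:
    """Serialize a fitted transformer to a JSON-ready dict."""
    name = next(k for k, v in PRETREATMENTS.items() if isinstance(tr, v))
    return {"method": name, "state": tr.get_state()}


def pretreatment_from_state(payload: dict) -> _SpectralTransformer:
    cls = PRETREATMENTS[payload["method"]]
    tr = cls.__new__(cls)
    # restore constructor defaults before applying state
    cls.__init__(tr)
    return tr.set_state(payload["state"])


def fit_error_if_empty(X):
    if X is None or len(X) == 0:
        raise FitError("calibration set is empty")
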