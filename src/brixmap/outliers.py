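"""Monte Carlo PLS (MCPLS) abnormal-sample screening.

Reference values measured by refractometry occasionally disagree with the
spectrum they are paired with (juicing errors, instrument drift).  MCPLS
exposes such samples by repeatedly splitting the data at random into a
calibration and a prediction part, fitting a PLS regression on the
calibration part, and recording each prediction-part sample's absolute
residual |y_hat - y|.  Over many splits every sample accumulates a residual
distribution; its mean (MPRE) and standard deviation (STDPRE) are large for
samples the rest of the data cannot explain.  A sample is flagged abnormal
only when it exceeds both cuts jointly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.cross_decomposition import PLSRegression
from sklearn.utils.validation import check_X_y

from .cube_io import SpectraTable
from .errors import ConfigError, CoverageError, ThresholdError


@dataclass
class OutlierReport:
    """Per-sample MCPLS residual statistics and joint-exceedance flags."""

    mpre: np.ndarray
    stdpre: np.ndarray
    n_appearances: np.ndarray
    flags: np.ndarray
    thresholds: tuple[float, float] | None
    settings: dict

    @property
    def n_flagged(self) -> int:
        return int(self.flags.sum())

    def flagged_indices(self) -> np.ndarray:
        return np.flatnonzero(self.flags)

    def retained_indices(self) -> np.ndarray:
        return np.flatnonzero(~self.flags)

    def to_frame(self, sample_ids=None) -> pd.DataFrame:
        n = self.mpre.size
        ids = sample_ids if sample_ids is not None else [f"s{i:04d}" for i in range(n)]
        return pd.DataFrame(
            {
                "sample_id": ids,
                "mpre": self.mpre,
                "stdpre": self.stdpre,
                "n_appearances": self.n_appearances,
                "flag": self.flags,
            }
        )

    def to_csv(self, path, sample_ids=None) -> None:
        self.to_frame(sample_ids).to_csv(path, index=False)


class MCPLSScreener(BaseEstimator):
    """Monte Carlo PLS outlier detector.

    Parameters
    ----------
    n_iter : number of random calibration/prediction splits.  500 is
        adequate for screening; the full published protocol uses 5000.
    cal_frac : fraction of samples assigned to the calibration part of each
        split (0.75 in the published protocol).
    n_components : PLS rank used inside every split.  Kept moderate (10) so
        sub-sampled calibration sets stay well conditioned.
    mpre_cut, stdpre_cut : optional joint thresholds; when None the fitted
        report carries no flags until :meth:`flag` or :meth:`auto_threshold`
        is called.
    random_state : seed for the split stream; fixed seed gives an exactly
        reproducible report.

    Attributes (after ``fit``)
    ----------
    mpre_, stdpre_, n_appearances_, flags_ : per-sample arrays
    report_ : the assembled :class:`OutlierReport`
    """

    def __init__(
        self,
        n_iter: int = 500,
        cal_frac: float = 0.75,
        n_components: int = 10,
        mpre_cut: float | None = None,
        stdpre_cut: float | None = None,
        random_state: int | None = 0,
    ):
        self.n_iter = n_iter
        self.cal_frac = cal_frac
        self.n_components = n_components
        self.mpre_cut = mpre_cut
        self.stdpre_cut = stdpre_cut
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y, y_numeric=True)
        n = X.shape[0]
        if not 0.0 < self.cal_frac < 1.0:
            raise ConfigError("cal_frac must be in (0, 1)")
        n_cal = int(round(self.cal_frac * n))
        n_cal = min(max(n_cal, 2), n - 1)
        if self.n_components >= n_cal:
            raise ConfigError(
                f"n_components={self.n_components} must be < calibration size {n_cal}"
            )
        rng = np.random.default_rng(self.random_state)

        count = np.zeros(n, dtype=int)
        s1 = np.zeros(n)  # running sum of residuals
        s2 = np.zeros(n)  # running sum of squared residuals
        ncomp = min(self.n_components, X.shape[1])
        for _ in range(self.n_iter):
            perm = rng.permutation(n)
            cal, pred = perm[:n_cal], perm[n_cal:]
            pls = PLSRegression(n_components=ncomp, scale=False)
            pls.fit(X[cal], y[cal])
            resid = np.abs(pls.predict(X[pred]).ravel() - y[pred])
            count[pred] += 1
            s1[pred] += resid
            s2[pred] += resid**2

        if np.any(count < 2):
            never = np.flatnonzero(count < 2).tolist()
            raise CoverageError(
                f"samples {never[:10]} appeared in <2 prediction sets after "
                f"{self.n_iter} iterations; increase n_iter"
            )
        mpre = s1 / count
        var = (s2 - count * mpre**2) / (count - 1)
        stdpre = np.sqrt(np.clip(var, 0.0, None))

        self.mpre_ = mpre
        self.stdpre_ = stdpre
        self.n_appearances_ = count
        if self.mpre_cut is not None and self.stdpre_cut is not None:
            self.flags_ = (mpre > self.mpre_cut) & (stdpre > self.stdpre_cut)
            thr = (float(self.mpre_cut), float(self.stdpre_cut))
        else:
            self.flags_ = np.zeros(n, dtype=bool)
            thr = None
        self.report_ = OutlierReport(
            mpre=mpre,
            stdpre=stdpre,
            n_appearances=count,
            flags=self.flags_,
            thresholds=thr,
            settings={
                "n_iter": self.n_iter,
                "cal_frac": self.cal_frac,
                "n_components": self.n_components,
                "seed": self.random_state,
            },
        )
        return self

    def predict(self, X=None):
        """sklearn outlier-detector convention: -1 for flagged, +1 otherwise."""
        return np.where(self.flags_, -1, 1)


def run_mcpls(
    data: SpectraTable,
    n_iter: int = 500,
    cal_frac: float = 0.75,
    n_components: int = 10,
    seed: int | None = 0,
) -> OutlierReport:
    """Functional wrapper over :class:`MCPLSScreener`."""
    if data.y is None:
        raise ConfigError("MCPLS requires reference values (data.y)")
    screener = MCPLSScreener(
        n_iter=n_iter, cal_frac=cal_frac, n_components=n_components, random_state=seed
    )
    screener.fit(data.x, data.y)
    return screener.report_


def flag_outliers(report: OutlierReport, mpre_cut: float, stdpre_cut: float) -> OutlierReport:
    """Joint-exceedance flagging: abnormal iff MPRE > cut AND STDPRE > cut."""
    flags = (report.mpre > mpre_cut) & (report.stdpre > stdpre_cut)
    return OutlierReport(
        mpre=report.mpre,
        stdpre=report.stdpre,
        n_appearances=report.n_appearances,
        flags=flags,
        thresholds=(float(mpre_cut), float(stdpre_cut)),
        settings=report.settings,
    )


def auto_threshold(report: OutlierReport, k: float = 3.0) -> tuple[float, float]:
    """Reproducible default cuts: mean + k*SD of each residual statistic.

    The published workflow picks cuts by eye from the MPRE/STDPRE scatter;
    this is the scripted stand-in.  A zero-variance statistic degenerates to
    its (constant) mean; if both statistics are constant there is nothing to
    threshold and an error is raised.
    """
    if np.std(report.mpre) == 0 and np.std(report.stdpre) == 0:
        raise ThresholdError("both MPRE and STDPRE distributions are degenerate")
    mpre_cut = float(report.mpre.mean() + k * report.mpre.std(ddof=1))
    stdpre_cut = float(report.stdpre.mean() + k * report.stdpre.std(ddof=1))
    return mpre_cut, stdpre_cut
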