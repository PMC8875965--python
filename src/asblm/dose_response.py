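"""Relative root elongation and sigmoidal dose-response fitting.

The hydroponic endpoint is relative root elongation,

    RRE = 100 * (Lf_t - Li_t) / (Lf_c - Li_c)   [%],

computed from mean initial/final root lengths per treatment.  RRE against
the natural log of the As(V) exposure (activity or concentration) is fitted
with the four-parameter logistic

    y = y0 + a / (1 + exp(-(x - x0) / b)),

and EC50 is the exposure where the fitted curve crosses y = 50 (absolute
percent of control, which coincides with the curve midpoint x0 for a
full-range 0-100 curve).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator, RegressorMixin

from .blm import ECEstimate

__all__ = [
    "compute_rre",
    "logistic4",
    "LogisticDoseResponse",
    "fit_dose_response",
    "ec50_from_fit",
]

#: Default seed for the parametric bootstrap on EC50 uncertainty.
BOOTSTRAP_SEED = 20220208

ROOT_COLUMNS = ("medium_label", "as_total_uM", "seed_id",
                "length_initial_mm", "length_final_mm", "is_control")


def compute_rre(records: pd.DataFrame) -> pd.DataFrame:
    """Per-treatment relative root elongation from a root-length table.

    ``records`` needs columns ``as_total_uM``, ``length_initial_mm``,
    ``length_final_mm`` and ``is_control`` (one row per seed).  Returns one
    row per treatment with the mean elongation and RRE in percent; the
    control rows yield RRE = 100 by construction.
    """
    missing = {"as_total_uM", "length_initial_mm", "length_final_mm",
               "is_control"} - set(records.columns)
    if missing:
        raise ValueError(f"root-length table lacks columns {sorted(missing)}")
    df = records.copy()
    df["elongation_mm"] = df["length_final_mm"] - df["length_initial_mm"]
    if (df["elongation_mm"] < 0).any():
        n = int((df["elongation_mm"] < 0).sum())
        df.attrs["n_negative_elongation"] = n  # flagged, not rejected
    control = df.loc[df["is_control"].astype(bool), "elongation_mm"].mean()
    if not np.isfinite(control) or control <= 0:
        raise ValueError(f"control mean elongation must be > 0, got {control}")
    out = (df.groupby("as_total_uM", as_index=False)
             .agg(mean_elongation_mm=("elongation_mm", "mean"),
                  n_seeds=("elongation_mm", "size")))
    out["rre_percent"] = 100.0 * out["mean_elongation_mm"] / control
    return out


def logistic4(x, a, b, x0, y0):
    """Four-parameter logistic y = y0 + a / (1 + exp(-(x - x0)/b))."""
    with np.errstate(over="ignore"):  # exp overflow saturates y at y0
        return y0 + a / (1.0 + np.exp(-(np.asarray(x, dtype=float) - x0) / b))


class LogisticDoseResponse(BaseEstimator, RegressorMixin):
    """Four-parameter logistic dose-response curve as a fit/predict estimator.

    ``fit`` takes x (natural log of exposure, one value per treatment) and
    y (RRE in percent) and runs nonlinear least squares with a deterministic
    initialisation: y0 = min(y), a = max(y) - min(y), x0 = median(x),
    |b| = range(x)/6 with the sign of the observed trend.  EC50 is the
    exposure at which the fitted curve crosses 50%, with a parametric
    bootstrap standard deviation drawn from the parameter covariance.
    """

    def __init__(self, ec50_level: float = 50.0, maxfev: int = 10000):
        self.ec50_level = ec50_level
        self.maxfev = maxfev

    def fit(self, x, y) -> "LogisticDoseResponse":
        x = np.asarray(x, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        if x.shape != y.shape:
            raise ValueError("x and y must have the same length")
        if np.unique(x).size < 5:
            raise ValueError("need >= 5 distinct exposure levels")
        if np.ptp(y) == 0:
            raise ValueError("response is constant; dose-response fit is degenerate")
        trend = np.polyfit(x, y, 1)[0]
        b0 = np.ptp(x) / 6.0 * (1.0 if trend >= 0 else -1.0)
        p0 = (np.ptp(y), b0, float(np.median(x)), float(np.min(y)))
        try:
            popt, pcov = curve_fit(logistic4, x, y, p0=p0, maxfev=self.maxfev)
            ok = np.all(np.isfinite(popt)) and np.all(np.isfinite(pcov))
        except RuntimeError:
            popt, pcov, ok = np.full(4, np.nan), np.full((4, 4), np.nan), False
        self.a_, self.b_, self.x0_, self.y0_ = (float(v) for v in popt)
        self.cov_ = np.asarray(pcov, dtype=float)
        self.converged_ = bool(ok) and self.b_ != 0.0
        self.x_range_ = (float(x.min()), float(x.max()))
        return self

    def predict(self, x) -> np.ndarray:
        self._check_fitted()
        return np.asarray(logistic4(x, self.a_, self.b_, self.x0_, self.y0_))

    def _check_fitted(self) -> None:
        if not hasattr(self, "converged_"):
            raise RuntimeError("estimator is not fitted")
        if not self.converged_:
            raise RuntimeError("dose-response fit did not converge")

    @staticmethod
    def _ec50_x(a, b, x0, y0, level):
        """ln-exposure where the logistic crosses ``level``; NaN if it cannot."""
        with np.errstate(divide="ignore", invalid="ignore"):
            e = a / (level - y0) - 1.0
            return np.where(e > 0, x0 - b * np.log(e), np.nan)

    def ec50_x(self) -> float:
        """Natural log of the exposure at the 50% crossing."""
        self._check_fitted()
        x = float(self._ec50_x(self.a_, self.b_, self.x0_, self.y0_, self.ec50_level))
        if not np.isfinite(x):
            raise ValueError(
                f"fitted curve never crosses {self.ec50_level}% "
                f"(a={self.a_:.3g}, y0={self.y0_:.3g})")
        return x

    def ec50(self, n_boot: int = 1000, seed: int = BOOTSTRAP_SEED) -> ECEstimate:
        """EC50 on the exposure scale with a parametric-bootstrap sd.

        Draws parameter vectors from N(theta_hat, cov), recomputes the 50%
        crossing for each and takes the standard deviation of the exposures;
        draws whose curve misses 50% are dropped.
        """
        x50 = self.ec50_x()
        value = float(np.exp(x50))
        sd = 0.0
        if n_boot > 0 and np.all(np.isfinite(self.cov_)):
            rng = np.random.default_rng(seed)
            draws = rng.multivariate_normal(
                [self.a_, self.b_, self.x0_, self.y0_], self.cov_,
                size=n_boot, method="svd")
            xs = self._ec50_x(draws[:, 0], draws[:, 1], draws[:, 2],
                              draws[:, 3], self.ec50_level)
            vals = np.exp(xs[np.isfinite(xs)])
            if vals.size > 1:
                sd = float(np.std(vals, ddof=1))
        return ECEstimate(value=value, sd=sd, basis="measured")


def fit_dose_response(x, y) -> LogisticDoseResponse:
    """Thin functional wrapper over :class:`LogisticDoseResponse`."""
    return LogisticDoseResponse().fit(x, y)


def ec50_from_fit(fit: LogisticDoseResponse, n_boot: int = 1000,
                  seed: int = BOOTSTRAP_SEED) -> ECEstimate:
    """EC50 (exposure scale) with bootstrap sd from a converged fit."""
    return fit.ec50(n_boot=n_boot, seed=seed)
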