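"""Biotic ligand model for arsenate and its interspecies extrapolation.

The model writes the 50% effect level, expressed as the bulk HAsO4 2-
activity, as a product of a species-specific inherent sensitivity

    IS = f50 / (1 - f50)            (f50: fraction of active binding sites
                                     occupied by arsenate at 50% effect)

and a medium-specific environmental modulator

    EM = (1 + K_XH2PO4 {H2PO4-} + K_XHPO4 {HPO4 2-})
         / (K_XH2AsO4 {H+} / K_As + K_XHAsO4)

so EC50{HAsO4 2-} = IS x EM.  Phosphate competes for the binding sites
(raising EM alleviates toxicity); the pH term converts between the two
arsenate protonation states.  On top of this, a linear correction in the
membrane surface potential psi0 captures the electrostatic accumulation of
arsenate anions at depolarised (less negative) membrane surfaces:

    EC50_site = EC50_ini + p (psi0_site - psi0_ini),   p in uM/mV.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from .constants import BLMConstants, DEFAULT_BLM_CONSTANTS, PUBLISHED_PSI0_FITS
from .speciation import SpeciationResult

__all__ = [
    "SensitivityRecord",
    "PsiSlopeFit",
    "ECEstimate",
    "environmental_modulator",
    "ec50_blm",
    "inherent_sensitivity",
    "predict_ec50_site",
    "psi0_adjust",
    "normalized_ec50",
    "fit_psi0_slope",
    "ExtrapolatedBLM",
]


@dataclass(frozen=True)
class SensitivityRecord:
    """Per-species inherent sensitivity: f50 and IS = f50/(1-f50)."""

    species: str
    endpoint: str
    f_mix50: float
    IS: float

    def __post_init__(self) -> None:
        if not 0.0 < self.f_mix50 < 1.0:
            raise ValueError(f"f_mix50 must be in (0, 1), got {self.f_mix50}")

    @classmethod
    def from_f(cls, f_mix50: float, species: str = "", endpoint: str = "") -> "SensitivityRecord":
        if not 0.0 < f_mix50 < 1.0:
            raise ValueError(f"f_mix50 must be in (0, 1), got {f_mix50}")
        return cls(species, endpoint, f_mix50, f_mix50 / (1.0 - f_mix50))


@dataclass(frozen=True)
class PsiSlopeFit:
    """Linear psi0 -> EC50 relation: EC50 [uM] = intercept + slope * psi0 [mV]."""

    species: str
    slope: float  # uM per mV
    intercept: float  # uM, EC50 at psi0 = 0
    r_squared: float


@dataclass(frozen=True)
class ECEstimate:
    """EC50 expressed as HAsO4 2- activity (mol/L)."""

    value: float
    sd: float = 0.0
    basis: str = "measured"  # measured | blm | blm+psi0

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError(f"EC50 must be > 0, got {self.value}")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


def environmental_modulator(spec: SpeciationResult,
                            constants: BLMConstants = DEFAULT_BLM_CONSTANTS) -> float:
    """Medium-specific modulator EM (mol/L): phosphate competition numerator
    over the pH-weighted arsenate binding denominator."""
    numer = (1.0
             + constants.K_XH2PO4 * spec.activity("H2PO4-")
             + constants.K_XHPO4 * spec.activity("HPO42-"))
    denom = (constants.K_XH2AsO4 * spec.activity("H+") / constants.K_As
             + constants.K_XHAsO4)
    return numer / denom


def ec50_blm(f_mix50: float, spec: SpeciationResult,
             constants: BLMConstants = DEFAULT_BLM_CONSTANTS) -> ECEstimate:
    """EC50{HAsO4 2-} = [f/(1-f)] x EM for a species with site occupancy f."""
    if not 0.0 < f_mix50 < 1.0:
        raise ValueError(f"f_mix50 must be in (0, 1), got {f_mix50}")
    value = f_mix50 / (1.0 - f_mix50) * environmental_modulator(spec, constants)
    return ECEstimate(value=value, basis="blm")


def inherent_sensitivity(ec50_measured: float, em: float,
                         species: str = "", endpoint: str = "") -> SensitivityRecord:
    """Calibrate IS (and f50) from one measured EC50 and the test-medium EM."""
    if ec50_measured <= 0 or em <= 0:
        raise ValueError("ec50_measured and em must be > 0")
    IS = ec50_measured / em
    return SensitivityRecord(species, endpoint, IS / (1.0 + IS), IS)


def predict_ec50_site(sens: SensitivityRecord, em_site: float) -> ECEstimate:
    """Site prediction EC50 = IS x EM_site (no psi0 correction)."""
    return ECEstimate(value=sens.IS * em_site, basis="blm")


def psi0_adjust(ec50_ini: ECEstimate, fit: PsiSlopeFit,
                psi0_site_mV: float, psi0_ini_mV: float,
                floor_fraction: float | None = 0.01) -> ECEstimate:
    """Linear psi0 correction: EC50_site = EC50_ini + p (psi0_site - psi0_ini).

    The slope p is in uM/mV (EC50 converted internally).  Outside the linear
    range the correction can drive EC50 <= 0; the result is then floored at
    ``floor_fraction`` x EC50_ini with a warning, or rejected if flooring is
    disabled (``floor_fraction=None``).
    """
    ini_uM = ec50_ini.value * 1e6
    adj_uM = ini_uM + fit.slope * (psi0_site_mV - psi0_ini_mV)
    if adj_uM <= 0:
        if floor_fraction is None:
            raise ValueError(
                f"psi0 adjustment drives EC50 to {adj_uM:.3g} uM "
                f"(ini {ini_uM:.3g} uM, dpsi0 {psi0_site_mV - psi0_ini_mV:.3g} mV)"
            )
        warnings.warn(
            f"psi0 adjustment gave EC50 = {adj_uM:.3g} uM <= 0; "
            f"flooring at {floor_fraction:g} x EC50_ini", stacklevel=2,
        )
        adj_uM = floor_fraction * ini_uM
    return ECEstimate(value=adj_uM * 1e-6, sd=ec50_ini.sd, basis="blm+psi0")


def normalized_ec50(ec50: ECEstimate, fit: PsiSlopeFit) -> float:
    """EC50 divided by the fitted EC50 at psi0 = 0 (the y-axis intercept);
    removes species sensitivity so the psi0 effect can be compared across
    species."""
    if fit.intercept <= 0:
        raise ValueError("intercept must be > 0 for normalization")
    return ec50.value * 1e6 / fit.intercept


def fit_psi0_slope(points, species: str = "") -> PsiSlopeFit:
    """Ordinary least squares of EC50 [uM] on psi0 [mV].

    ``points`` is an iterable of (psi0_mV, ec50_uM) pairs; at least three
    points are required (two points determine a line but give no residual
    information).
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3:
        raise ValueError("need at least 3 (psi0, ec50) points")
    psi, ec = pts[:, 0], pts[:, 1]
    if np.ptp(psi) == 0:
        raise ValueError("psi0 values are degenerate (no spread)")
    res = stats.linregress(psi, ec)
    return PsiSlopeFit(species=species, slope=float(res.slope),
                       intercept=float(res.intercept),
                       r_squared=float(res.rvalue ** 2))


def published_fit(species: str) -> PsiSlopeFit:
    """Published psi0-EC50 regression for a species, as a read-only constant.

    The per-Ca EC50 points behind these fits were published only graphically,
    so the slopes are consumed, never re-derived.  The intercept is
    reconstructed from the calibration anchor where available (NaN
    otherwise).
    """
    entry = PUBLISHED_PSI0_FITS[species]
    slope = entry.get("slope_uM_per_mV", entry.get("slope_per_mV"))
    return PsiSlopeFit(species=species, slope=slope, intercept=float("nan"),
                       r_squared=entry["r_squared"])


class ExtrapolatedBLM(BaseEstimator):
    """Interspecies-extrapolated arsenate BLM as a fit/predict estimator.

    ``fit`` calibrates the inherent sensitivity from a single measured EC50
    in a reference medium (the species' toxicity test); ``predict`` returns
    EC50{HAsO4 2-} for new media from their speciation, optionally with the
    linear psi0 correction relative to the reference medium.

    Parameters
    ----------
    constants : BLMConstants
        Conditional binding constants of the arsenate BLM.
    psi_slope : float or None
        Slope p of the psi0 correction in uM/mV.  ``None`` disables the
        correction even when psi0 values are supplied.
    floor_fraction : float or None
        Floor for psi0-corrected EC50s, as a fraction of the uncorrected
        value; ``None`` raises instead of flooring.

    Attributes
    ----------
    sensitivity_ : SensitivityRecord
        Calibrated f50 and IS.
    em_ref_ : float
        Environmental modulator of the reference medium (mol/L).
    psi0_ref_mV_ : float or None
        Reference-medium surface potential, if supplied to ``fit``.
    """

    def __init__(self, constants: BLMConstants = DEFAULT_BLM_CONSTANTS,
                 psi_slope: float | None = None,
                 floor_fraction: float | None = 0.01):
        self.constants = constants
        self.psi_slope = psi_slope
        self.floor_fraction = floor_fraction

    def fit(self, reference_spec: SpeciationResult, ec50_measured: float,
            psi0_ref_mV: float | None = None, species: str = "",
            endpoint: str = "") -> "ExtrapolatedBLM":
        self.em_ref_ = environmental_modulator(reference_spec, self.constants)
        self.sensitivity_ = inherent_sensitivity(
            ec50_measured, self.em_ref_, species=species, endpoint=endpoint)
        self.psi0_ref_mV_ = psi0_ref_mV
        self.ec50_ref_ = ECEstimate(value=ec50_measured, basis="measured")
        return self

    def predict(self, specs, psi0_mV=None) -> np.ndarray:
        """EC50{HAsO4 2-} (mol/L) for each medium speciation in ``specs``.

        If ``psi0_mV`` is given (one value per medium) and the estimator has
        a psi0 slope and reference potential, the linear correction is
        applied on top of the IS x EM prediction.
        """
        if not hasattr(self, "sensitivity_"):
            raise RuntimeError("estimator is not fitted")
        estimates = self.predict_estimates(specs, psi0_mV)
        return np.array([e.value for e in estimates])

    def predict_estimates(self, specs, psi0_mV=None) -> list[ECEstimate]:
        if not hasattr(self, "sensitivity_"):
            raise RuntimeError("estimator is not fitted")
        specs = list(specs)
        use_psi = (psi0_mV is not None and self.psi_slope is not None
                   and self.psi0_ref_mV_ is not None)
        if psi0_mV is not None and len(psi0_mV) != len(specs):
            raise ValueError("psi0_mV must have one entry per medium")
        out = []
        for i, spec in enumerate(specs):
            est = predict_ec50_site(self.sensitivity_,
                                    environmental_modulator(spec, self.constants))
            if use_psi:
                fit = PsiSlopeFit("", self.psi_slope, float("nan"), float("nan"))
                est = psi0_adjust(est, fit, psi0_mV[i], self.psi0_ref_mV_,
                                  floor_fraction=self.floor_fraction)
            out.append(est)
        return out


def within_order_of_magnitude(predicted: float, measured: float) -> bool:
    """Band criterion for measured-vs-predicted EC50s: |log10 ratio| <= 1."""
    if predicted <= 0 or measured <= 0:
        raise ValueError("EC50s must be > 0")
    return abs(np.log10(predicted / measured)) <= 1.0
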