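"""End-to-end analysis stages composing the library modules.

Each stage is a plain function over data frames / domain objects; the CLI
wraps these one-to-one, so command output always equals direct library
calls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .blm import (
    ExtrapolatedBLM,
    PsiSlopeFit,
    environmental_modulator,
    fit_psi0_slope,
    inherent_sensitivity,
    psi0_adjust,
    within_order_of_magnitude,
)
from .constants import (
    BLMConstants,
    DEFAULT_BLM_CONSTANTS,
    MEASURED_EC50_HVULGARE,
    PUBLISHED_PSI0_FITS,
    SENSITIVITY_REGISTRY,
)
from .dose_response import LogisticDoseResponse, compute_rre
from .membrane import MembraneParams, default_membrane_params, solve_psi0
from .simulate import SimulatedStudy
from .speciation import (
    MediumComposition,
    speciate_medium,
    speciation_to_frame,
)

__all__ = [
    "speciate_table",
    "psi0_table",
    "fit_ec50_table",
    "StudyRecovery",
    "recover_study",
    "prediction_table",
    "reference_anchor_report",
]


def speciate_table(media: list[MediumComposition]) -> pd.DataFrame:
    """Speciation of every medium, long format."""
    return speciation_to_frame([speciate_medium(m) for m in media])


def psi0_table(media: list[MediumComposition],
               params: MembraneParams | None = None) -> pd.DataFrame:
    """Surface potential and charge density per medium."""
    params = params or default_membrane_params()
    rows = []
    for m in media:
        state = solve_psi0(speciate_medium(m), params)
        rows.append({
            "label": m.label, "psi0_mV": state.psi0_mV, "sigma_C_m2": state.sigma,
            "residual": state.residual, "converged": state.converged,
            "surface_HAsO42-_M": state.surface_activities.get("HAsO42-", 0.0),
            "surface_H2AsO4-_M": state.surface_activities.get("H2AsO4-", 0.0),
        })
    return pd.DataFrame(rows)


def _activity_for_dose(base: MediumComposition, dose_uM: float) -> float:
    """Bulk HAsO4 2- activity when a total As(V) dose is added to a medium."""
    totals = dict(base.totals)
    totals["As_total"] = dose_uM * 1e-6
    totals["Na"] = totals.get("Na", 0.0) + 2.0 * dose_uM * 1e-6  # Na2HAsO4 salt
    from dataclasses import replace

    dosed = replace(base, totals=totals,
                    label=f"{base.label}_As{dose_uM:g}uM").with_charge_balance()
    return speciate_medium(dosed).activity("HAsO42-")


def fit_ec50_table(media: list[MediumComposition], roots: pd.DataFrame,
                   n_boot: int = 1000) -> pd.DataFrame:
    """Dose-response fit and EC50 (as HAsO4 2- activity) per medium.

    ``roots`` is a per-seed root-length table; doses are converted to
    HAsO4 2- activities by re-speciating each medium with its As dose
    before fitting RRE against ln activity.
    """
    by_label = {m.label: m for m in media}
    rows = []
    for label, grp in roots.groupby("medium_label"):
        base = by_label[label]
        rre = compute_rre(grp)
        treated = rre[rre["as_total_uM"] > 0]
        x = np.log([_activity_for_dose(base, d) for d in treated["as_total_uM"]])
        fit = LogisticDoseResponse().fit(x, treated["rre_percent"].to_numpy())
        row = {"medium_label": label, "a": fit.a_, "b": fit.b_, "x0": fit.x0_,
               "y0": fit.y0_, "converged": fit.converged_,
               "ec50_activity_M": np.nan, "ec50_sd_M": np.nan}
        if fit.converged_:
            est = fit.ec50(n_boot=n_boot)
            row["ec50_activity_M"] = est.value
            row["ec50_sd_M"] = est.sd
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class StudyRecovery:
    """Calibration-and-slope inversion of one (synthetic or real) study."""

    ec50s: pd.DataFrame  # per medium: psi0_mV, em_M, ec50_activity_M
    f_mix50: float
    IS: float
    slope_fit: PsiSlopeFit


def recover_study(study: SimulatedStudy, params: MembraneParams | None = None,
                  constants: BLMConstants = DEFAULT_BLM_CONSTANTS,
                  n_boot: int = 0) -> StudyRecovery:
    """Run the full estimation pipeline on a study.

    Fits per-medium EC50s, calibrates f50/IS on the first (lowest-Ca)
    medium, and fits the psi0-EC50 line across the ladder — the inverse of
    the generator's forward model.
    """
    params = params or default_membrane_params()
    ec50s = fit_ec50_table(study.media, study.roots, n_boot=n_boot)
    psi = psi0_table(study.media, params)
    merged = ec50s.merge(psi.rename(columns={"label": "medium_label"}),
                         on="medium_label")
    by_label = {m.label: m for m in study.media}
    merged["em_M"] = [environmental_modulator(speciate_medium(by_label[l]), constants)
                      for l in merged["medium_label"]]
    ref_label = study.media[0].label
    ref = merged[merged["medium_label"] == ref_label].iloc[0]
    sens = inherent_sensitivity(float(ref["ec50_activity_M"]), float(ref["em_M"]))
    pts = merged.dropna(subset=["ec50_activity_M"])
    slope = fit_psi0_slope(
        list(zip(pts["psi0_mV"], pts["ec50_activity_M"] * 1e6)))
    return StudyRecovery(ec50s=merged, f_mix50=sens.f_mix50, IS=sens.IS,
                         slope_fit=slope)


def prediction_table(model: ExtrapolatedBLM, media: list[MediumComposition],
                     measured_M: dict[str, float] | None = None,
                     params: MembraneParams | None = None) -> pd.DataFrame:
    """Measured-vs-predicted EC50 table with order-of-magnitude band flags."""
    params = params or default_membrane_params()
    specs = [speciate_medium(m) for m in media]
    psi0 = [solve_psi0(s, params).psi0_mV for s in specs]
    ests = model.predict_estimates(specs, psi0_mV=psi0)
    rows = []
    for m, s, p, est in zip(media, specs, psi0, ests):
        row = {"label": m.label, "em_M": environmental_modulator(s, model.constants),
               "is": model.sensitivity_.IS, "psi0_mV": p,
               "ec50_predicted_M": est.value, "basis": est.basis}
        if measured_M and m.label in measured_M:
            meas = measured_M[m.label]
            row["ec50_measured_M"] = meas
            row["within_order_of_magnitude"] = within_order_of_magnitude(
                est.value, meas)
        rows.append(row)
    return pd.DataFrame(rows)


def reference_anchor_report(constants: BLMConstants = DEFAULT_BLM_CONSTANTS,
                            params: MembraneParams | None = None) -> pd.DataFrame:
    """Recompute the model's reference quantities on the study media.

    Runs the chain on the vendored medium definitions: the four psi0
    anchors, the background-medium EM, the calibrated IS/f50 from the
    measured barley EC50, the Ca-ladder fold decrease of the measured
    EC50s, and the psi0-corrected EC50 prediction at 20 mM Ca.  Returns a
    (quantity, computed, reported) table; the reported column holds the
    published values for side-by-side display only.
    """
    params = params or default_membrane_params()
    rows = []

    anchor_media = [
        ("psi0_plant_Ca0.2mM_mV", MediumComposition.background_plant(0.2), -53.8),
        ("psi0_plant_Ca20mM_mV", MediumComposition.background_plant(20.0), -3.3),
        ("psi0_fischeri_Ca0mM_mV", MediumComposition.fischeri_saline(0.0), -13.7),
        ("psi0_fischeri_Ca25mM_mV", MediumComposition.fischeri_saline(25.0), -0.4),
    ]
    psi_by_name = {}
    for name, medium, reported in anchor_media:
        state = solve_psi0(speciate_medium(medium), params)
        psi_by_name[name] = state.psi0_mV
        rows.append({"quantity": name, "computed": state.psi0_mV,
                     "reported": reported})

    ref_spec = speciate_medium(MediumComposition.background_plant(0.2))
    em = environmental_modulator(ref_spec, constants)
    rows.append({"quantity": "EM_background_M", "computed": em,
                 "reported": 2.70e-5})

    (ec50_low, _), (ec50_high_ca, _) = (MEASURED_EC50_HVULGARE[0.2e-3],
                                        MEASURED_EC50_HVULGARE[20e-3])
    sens = inherent_sensitivity(ec50_low, em, species="H. vulgare")
    rows.append({"quantity": "IS_H_vulgare", "computed": sens.IS,
                 "reported": 1.675})
    rows.append({"quantity": "f_mix50_H_vulgare", "computed": sens.f_mix50,
                 "reported": 0.626})
    rows.append({"quantity": "ec50_fold_decrease_Ca_ladder",
                 "computed": ec50_low / ec50_high_ca, "reported": 3.02})

    slope = PsiSlopeFit("H. vulgare",
                        PUBLISHED_PSI0_FITS["H. vulgare"]["slope_uM_per_mV"],
                        float("nan"), PUBLISHED_PSI0_FITS["H. vulgare"]["r_squared"])
    from .blm import ECEstimate

    adj = psi0_adjust(ECEstimate(value=ec50_low, basis="blm"), slope,
                      psi_by_name["psi0_plant_Ca20mM_mV"],
                      psi_by_name["psi0_plant_Ca0.2mM_mV"])
    rows.append({"quantity": "ec50_predicted_Ca20mM_uM",
                 "computed": adj.value * 1e6, "reported": 14.0})
    rows.append({"quantity": "ec50_measured_Ca20mM_uM",
                 "computed": ec50_high_ca * 1e6, "reported": 15.0})
    return pd.DataFrame(rows)
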