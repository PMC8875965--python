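"""Synthetic hydroponic root-elongation studies from the forward model.

Generates complete studies — a Ca2+ ladder of media, true psi0/EC50 values
via speciation -> GCS -> IS x EM -> psi0 correction, and noisy per-seed
root-length tables whose expected relative root elongation follows the
four-parameter logistic around the true EC50.  The generator and the
estimation pipeline deliberately share one forward model: recovering the
injected parameters tests the code end to end, not the biology.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .blm import (
    ECEstimate,
    PsiSlopeFit,
    SensitivityRecord,
    environmental_modulator,
    predict_ec50_site,
    psi0_adjust,
)
from .constants import BLMConstants, DEFAULT_BLM_CONSTANTS
from .membrane import MembraneParams, default_membrane_params, solve_psi0
from .speciation import MediumComposition, speciate_medium

__all__ = ["SimulationConfig", "SimulatedStudy", "simulate_study"]


@dataclass(frozen=True)
class SimulationConfig:
    """Study design and noise model for the synthetic generator.

    Defaults mirror the hydroponic test design: a Ca ladder of 0.2, 1, 5,
    10, 20 mM, seven As(V) treatments (0, 0.5, 2, 10, 50, 200, 1000 uM)
    with six seeds each, and additive Gaussian noise on per-seed elongation
    scaled to 5% of the control elongation.  Control elongation (60 +- 6 mm
    over 5 days) and initial root length (10 +- 1 mm) are generator choices
    at the scale typical of 5-day barley seedlings.
    """

    seed: int = 0
    species_f_mix50: float = 0.626
    psi_slope_p: float = -0.615  # uM per mV
    ca_ladder_mM: tuple[float, ...] = (0.2, 1.0, 5.0, 10.0, 20.0)
    as_doses_uM: tuple[float, ...] = (0.0, 0.5, 2.0, 10.0, 50.0, 200.0, 1000.0)
    seeds_per_treatment: int = 6
    noise_sd_rre: float = 5.0  # percent RRE
    control_elongation_mm: tuple[float, float] = (60.0, 6.0)  # mean, sd between media
    initial_length_mm: tuple[float, float] = (10.0, 1.0)
    logistic_b: float = -0.7  # slope of the true curve in ln-activity units
    logistic_a: float = 100.0
    logistic_y0: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.species_f_mix50 < 1.0:
            raise ValueError("species_f_mix50 must be in (0, 1)")
        if 0.0 not in self.as_doses_uM:
            raise ValueError("as_doses_uM must include the 0 (control) dose")
        if self.seeds_per_treatment < 1:
            raise ValueError("need at least one seed per treatment")
        if self.noise_sd_rre < 0:
            raise ValueError("noise_sd_rre must be >= 0")


@dataclass
class SimulatedStudy:
    """Generated study: media, per-seed root lengths, and the truth table."""

    config: SimulationConfig
    media: list[MediumComposition]
    roots: pd.DataFrame
    truth: pd.DataFrame  # ca_mM, psi0_mV, em_M, ec50_ini_M, ec50_true_M

    def write(self, outdir) -> dict[str, Path]:
        from .speciation import media_to_csv

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "media": outdir / "media.csv",
            "roots": outdir / "root_lengths.csv",
            "truth": outdir / "truth.csv",
        }
        media_to_csv(self.media, paths["media"])
        self.roots.to_csv(paths["roots"], index=False)
        self.truth.to_csv(paths["truth"], index=False)
        return paths


def _true_rre(ln_activity: float, ln_ec50: float, cfg: SimulationConfig) -> float:
    # y0 + a/(1+exp(-(x-x0)/b)) with x0 at the 50% crossing because y0=0, a=100
    # by default; for other (a, y0) shift x0 so the curve still crosses 50 there.
    a, b, y0 = cfg.logistic_a, cfg.logistic_b, cfg.logistic_y0
    e = a / (50.0 - y0) - 1.0
    x0 = ln_ec50 + b * np.log(e)
    return float(y0 + a / (1.0 + np.exp(-(ln_activity - x0) / b)))


def simulate_study(config: SimulationConfig,
                   constants: BLMConstants = DEFAULT_BLM_CONSTANTS,
                   params: MembraneParams | None = None) -> SimulatedStudy:
    """Generate one synthetic Ca-ladder study.

    For each Ca level the background plant medium is built and speciated,
    psi0 solved, and the true EC50 assembled as IS x EM (site baseline)
    plus the linear psi0 shift relative to the lowest-Ca (calibration)
    medium.  Per-seed final lengths are drawn so the expected RRE follows
    the logistic truth with the configured additive noise; lengths are
    truncated at 0 mm.  Output is byte-deterministic for a fixed seed.
    """
    params = params or default_membrane_params()
    rng = np.random.default_rng(config.seed)
    sens = SensitivityRecord.from_f(config.species_f_mix50, species="synthetic")
    slope = PsiSlopeFit("synthetic", config.psi_slope_p, float("nan"), float("nan"))

    media: list[MediumComposition] = []
    truth_rows = []
    root_rows = []
    psi0_ref = None
    for ca in config.ca_ladder_mM:
        medium = MediumComposition.background_plant(ca_mM=ca, label=f"sim_Ca{ca:g}mM")
        spec = speciate_medium(medium)
        state = solve_psi0(spec, params)
        em = environmental_modulator(spec, constants)
        ec50_ini = predict_ec50_site(sens, em)
        if psi0_ref is None:
            psi0_ref = state.psi0_mV
            ec50_true = ec50_ini
        else:
            ec50_true = psi0_adjust(ec50_ini, slope, state.psi0_mV, psi0_ref)
        media.append(medium)
        truth_rows.append({
            "medium_label": medium.label, "ca_mM": ca,
            "psi0_mV": state.psi0_mV, "em_M": em,
            "ec50_ini_M": ec50_ini.value, "ec50_true_M": ec50_true.value,
            "f_mix50": config.species_f_mix50, "psi_slope_p": config.psi_slope_p,
        })

        # per-medium control elongation (between-media biological variation)
        e_mean, e_sd = config.control_elongation_mm
        control_elong = max(rng.normal(e_mean, e_sd), 1.0)
        noise_sd_mm = config.noise_sd_rre / 100.0 * control_elong
        ln_ec50 = np.log(ec50_true.value)
        for dose in config.as_doses_uM:
            if dose == 0.0:
                rre_true = 100.0
            else:
                dosed = MediumComposition.background_plant(
                    ca_mM=ca, as_uM=dose, label=f"{medium.label}_As{dose:g}uM")
                act = speciate_medium(dosed).activity("HAsO42-")
                rre_true = _true_rre(np.log(act), ln_ec50, config)
            mean_elong = rre_true / 100.0 * control_elong
            for seed_id in range(config.seeds_per_treatment):
                li = max(rng.normal(*config.initial_length_mm), 0.0)
                elong = max(rng.normal(mean_elong, noise_sd_mm), 0.0)
                root_rows.append({
                    "medium_label": medium.label, "as_total_uM": dose,
                    "seed_id": seed_id,
                    "length_initial_mm": round(li, 3),
                    "length_final_mm": round(li + elong, 3),
                    "is_control": dose == 0.0,
                })

    return SimulatedStudy(
        config=config, media=media,
        roots=pd.DataFrame(root_rows),
        truth=pd.DataFrame(truth_rows),
    )
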