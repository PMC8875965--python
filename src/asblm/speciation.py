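"""Equilibrium speciation of hydroponic test media.

Computes ionic strength, Davies activity coefficients and acid-base
speciation of arsenate and phosphate for a defined medium at fixed pH.
Major cations and anions are treated as fully dissociated free ions; ion
pairing and the carbonate system are deliberately omitted (sub-percent
effects at these ionic strengths, see the methods note).  The MOPS pH
buffer is treated as chemically inert and zwitterionic (no contribution
to ionic strength at pH 7).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .constants import (
    ARSENATE_SPECIES,
    DAVIES_A,
    DAVIES_B,
    DAVIES_I_LIMIT,
    MAJOR_IONS,
    PHOSPHATE_SPECIES,
    PKA_ARSENATE,
    PKA_PHOSPHATE,
    PKW,
    SPECIES_CHARGE,
)

__all__ = [
    "MediumComposition",
    "SpeciationResult",
    "AcidityConstants",
    "ARSENIC_ACID",
    "PHOSPHORIC_ACID",
    "ionic_strength",
    "activity_coefficient",
    "speciate_acid",
    "speciate_medium",
    "media_from_csv",
    "media_to_csv",
    "speciation_to_frame",
]

#: Total keys a medium may carry (mol/L).
_TOTAL_KEYS = ("Ca", "Mg", "K", "Na", "Cl", "NO3", "SO4", "P_total", "As_total")

#: CSV column -> (totals key, scale to mol/L)
_CSV_COLUMNS = {
    "Ca_mM": ("Ca", 1e-3), "Mg_mM": ("Mg", 1e-3), "K_mM": ("K", 1e-3),
    "Na_mM": ("Na", 1e-3), "Cl_mM": ("Cl", 1e-3), "NO3_mM": ("NO3", 1e-3),
    "SO4_mM": ("SO4", 1e-3), "P_mM": ("P_total", 1e-3),
    "As_uM": ("As_total", 1e-6),
}


@dataclass(frozen=True)
class AcidityConstants:
    """Stepwise pKa values of a polyprotic oxyacid (25 degC)."""

    name: str
    species: tuple[str, ...]  # most protonated first
    pka: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.species) != len(self.pka) + 1:
            raise ValueError("need one more species than pKa steps")
        if any(b <= a for a, b in zip(self.pka, self.pka[1:])):
            raise ValueError(f"{self.name}: pKa steps must be strictly increasing")


ARSENIC_ACID = AcidityConstants("arsenic acid", ARSENATE_SPECIES, PKA_ARSENATE)
PHOSPHORIC_ACID = AcidityConstants("phosphoric acid", PHOSPHATE_SPECIES, PKA_PHOSPHATE)


@dataclass(frozen=True)
class MediumComposition:
    """Total dissolved composition of one test solution.

    ``totals`` maps element/ion names (``Ca``, ``Mg``, ``K``, ``Na``, ``Cl``,
    ``NO3``, ``SO4``, ``P_total``, ``As_total``) to total concentrations in
    mol/L.  ``buffer_concentration`` is the MOPS concentration; it is
    chemically inert in this model.
    """

    label: str
    pH: float = 7.0
    temperature: float = 25.0
    totals: dict[str, float] = field(default_factory=dict)
    buffer_concentration: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.pH < 14.0:
            raise ValueError(f"pH must be in (0, 14), got {self.pH}")
        if not 0.0 <= self.temperature <= 40.0:
            raise ValueError(f"temperature must be in [0, 40] degC, got {self.temperature}")
        for key, value in self.totals.items():
            if key not in _TOTAL_KEYS:
                raise ValueError(f"unknown total {key!r}; expected one of {_TOTAL_KEYS}")
            if value < 0:
                raise ValueError(f"negative concentration for {key}: {value}")
        if self.buffer_concentration < 0:
            raise ValueError("negative buffer concentration")

    def total(self, key: str) -> float:
        return self.totals.get(key, 0.0)

    # -- constructors for the two study media --------------------------------

    @classmethod
    def background_plant(cls, ca_mM: float = 0.2, as_uM: float = 0.0,
                         label: str | None = None) -> "MediumComposition":
        """Hydroponic plant test medium at pH 7 (MOPS buffered).

        Background: Mg 0.05, K 0.2, Na 1 mM, PO4 0.05, SO4 0.05, NO3 0.2 mM,
        with a configurable Ca ladder and an As(V) dose added as the
        disodium salt (2 Na+ per As).  Charge is closed with Cl-/Na+
        (acid/base used for pH adjustment).
        """
        medium = cls(
            label=label or f"plant_Ca{ca_mM:g}mM_As{as_uM:g}uM",
            pH=7.0,
            totals={
                "Ca": ca_mM * 1e-3, "Mg": 0.05e-3, "K": 0.2e-3,
                "Na": 1.0e-3 + 2.0 * as_uM * 1e-6,  # Na2HAsO4 counter-ion
                "P_total": 0.05e-3, "SO4": 0.05e-3, "NO3": 0.2e-3,
                "As_total": as_uM * 1e-6,
            },
            buffer_concentration=3.6e-3,
        )
        return medium.with_charge_balance()

    @classmethod
    def fischeri_saline(cls, ca_mM: float = 0.0, as_uM: float = 0.0,
                        label: str | None = None) -> "MediumComposition":
        """A. fischeri assay medium: 0.342 M NaCl osmotic control at pH 7."""
        medium = cls(
            label=label or f"fischeri_Ca{ca_mM:g}mM_As{as_uM:g}uM",
            pH=7.0,
            totals={
                "Na": 0.342 + 2.0 * as_uM * 1e-6, "Cl": 0.342,
                "Ca": ca_mM * 1e-3, "As_total": as_uM * 1e-6,
            },
        )
        return medium.with_charge_balance()

    def with_charge_balance(self) -> "MediumComposition":
        """Close the charge balance by topping up Cl- or Na+.

        Added salts bring their own counter-ions (CaCl2, NaCl, Na2HAsO4) and
        pH adjustment adds HCl or NaOH; this helper emulates that by adding
        whichever of Cl-/Na+ neutralises the net speciated charge at the
        medium's pH.
        """
        medium = self
        # Adding the counter-ion shifts gamma and the phosphate split a
        # little, so iterate the closure to numerical neutrality.
        for _ in range(8):
            spec = speciate_medium(medium, _balance_check=False)
            net = spec.net_charge()  # eq/L, >0 means excess cations
            if abs(net) < 1e-13:
                break
            totals = dict(medium.totals)
            if net > 0:
                totals["Cl"] = totals.get("Cl", 0.0) + net
            else:
                totals["Na"] = totals.get("Na", 0.0) - net
            medium = replace(medium, totals=totals)
        return medium


@dataclass
class SpeciationResult:
    """Free-species concentrations and activities for one medium."""

    label: str
    pH: float
    ionic_strength: float  # mol/L
    gamma: dict[int, float]  # |charge| -> activity coefficient
    concentrations: dict[str, float]  # species -> mol/L
    activities: dict[str, float]  # species -> mol/L

    def activity(self, species: str) -> float:
        return self.activities.get(species, 0.0)

    def concentration(self, species: str) -> float:
        return self.concentrations.get(species, 0.0)

    def charged_species(self) -> dict[str, int]:
        return {s: z for s, z in SPECIES_CHARGE.items()
                if z != 0 and s in self.concentrations}

    def net_charge(self) -> float:
        """Net charge of the speciated solution in eq/L."""
        return sum(self.concentrations.get(s, 0.0) * z
                   for s, z in SPECIES_CHARGE.items())

    def element_total(self, element: str) -> float:
        """Summed concentration over the protonation states of As or P."""
        group = ARSENATE_SPECIES if element == "As" else PHOSPHATE_SPECIES
        return sum(self.concentrations.get(s, 0.0) for s in group)


def ionic_strength(concentrations: dict[str, float] | MediumComposition) -> float:
    """Ionic strength I = 1/2 sum c_i z_i^2 (mol/L).

    Accepts either a species->concentration map (with charges looked up in
    the species table) or a raw medium, in which case a first-pass
    speciation at gamma=1 supplies the species distribution.
    """
    if isinstance(concentrations, MediumComposition):
        spec = speciate_medium(concentrations, refine=False, _balance_check=False)
        concentrations = spec.concentrations
    total = 0.0
    for species, conc in concentrations.items():
        if conc < 0:
            raise ValueError(f"negative concentration for {species}")
        z = SPECIES_CHARGE.get(species, 0)
        total += conc * z * z
    return 0.5 * total


def activity_coefficient(charge: int, I: float) -> float:
    """Davies single-ion activity coefficient at 25 degC.

    log10 gamma = -A z^2 (sqrt(I)/(1+sqrt(I)) - 0.3 I).  Neutral species
    get gamma = 1.  Above I = 0.5 mol/L the model is outside its validity
    range; a warning is emitted and the extrapolated value returned.
    """
    if I < 0:
        raise ValueError(f"ionic strength must be >= 0, got {I}")
    if charge == 0 or I == 0:
        return 1.0
    if I > DAVIES_I_LIMIT:
        warnings.warn(
            f"ionic strength {I:.3g} M exceeds the Davies validity limit "
            f"({DAVIES_I_LIMIT} M); activity coefficients are extrapolated",
            stacklevel=2,
        )
    sqrt_i = np.sqrt(I)
    log_g = -DAVIES_A * charge * charge * (sqrt_i / (1.0 + sqrt_i) - DAVIES_B * I)
    return float(10.0 ** log_g)


def _gamma_table(I: float) -> dict[int, float]:
    return {z: activity_coefficient(z, I) for z in range(4)}


def speciate_acid(
    total: float,
    pH: float,
    constants: AcidityConstants,
    gamma: dict[int, float] | None = None,
) -> tuple[dict[str, float], dict[str, float]]:
    """Distribute a polyprotic oxyacid total over its protonation states.

    Mass action with thermodynamic (activity-based) constants: for step j,
    Ka_j = {H+} {A_j} / {A_{j-1}} with activities {A} = gamma(|z|) [A].
    Returns ``(concentrations, activities)`` keyed by species name; the
    species concentrations sum to ``total`` exactly.
    """
    if total < 0:
        raise ValueError("total must be >= 0")
    gamma = gamma or {z: 1.0 for z in range(4)}
    a_h = 10.0 ** (-pH)
    # Unnormalised concentration weights relative to the fully protonated form.
    weights = [1.0]
    for j, pka in enumerate(constants.pka):
        ka = 10.0 ** (-pka)
        # [A_j]/[A_{j-1}] = Ka * gamma(j-1) / (aH * gamma(j))
        ratio = ka * gamma[j] / (a_h * gamma[j + 1])
        weights.append(weights[-1] * ratio)
    norm = sum(weights)
    conc = {sp: total * w / norm for sp, w in zip(constants.species, weights)}
    act = {sp: conc[sp] * gamma[abs(SPECIES_CHARGE[sp])] for sp in constants.species}
    return conc, act


def _speciate_at_gamma(medium: MediumComposition,
                       gamma: dict[int, float]) -> tuple[dict[str, float], dict[str, float]]:
    a_h = 10.0 ** (-medium.pH)
    a_oh = 10.0 ** (medium.pH - PKW)
    conc = {"H+": a_h / gamma[1], "OH-": a_oh / gamma[1]}
    act = {"H+": a_h, "OH-": a_oh}
    for total_key, species in MAJOR_IONS.items():
        c = medium.total(total_key)
        conc[species] = c
        act[species] = c * gamma[abs(SPECIES_CHARGE[species])]
    for total_key, acid in (("As_total", ARSENIC_ACID), ("P_total", PHOSPHORIC_ACID)):
        c_acid, a_acid = speciate_acid(medium.total(total_key), medium.pH, acid, gamma)
        conc.update(c_acid)
        act.update(a_acid)
    return conc, act


def speciate_medium(medium: MediumComposition, refine: bool = True,
                    _balance_check: bool = True) -> SpeciationResult:
    """Full speciation of a medium.

    One pass at gamma = 1 establishes the species distribution and a first
    ionic strength; a fixed second cycle re-evaluates the activity
    coefficients on the speciated concentrations (the distribution shifts
    by < 0.1% on a third cycle at these ionic strengths, so the iteration
    count is fixed rather than adaptive).
    """
    gamma = {z: 1.0 for z in range(4)}
    conc, act = _speciate_at_gamma(medium, gamma)
    I = ionic_strength(conc)
    if refine:
        for _ in range(2):
            gamma = _gamma_table(I)
            conc, act = _speciate_at_gamma(medium, gamma)
            I = ionic_strength(conc)
    if _balance_check:
        net = sum(conc.get(s, 0.0) * z for s, z in SPECIES_CHARGE.items())
        if abs(net) > 0.02 * max(2.0 * I, 1e-10):
            warnings.warn(
                f"medium {medium.label!r} is charge-imbalanced by {net:.3g} eq/L; "
                "Graham-equation sums assume electroneutrality",
                stacklevel=2,
            )
    return SpeciationResult(
        label=medium.label, pH=medium.pH, ionic_strength=I,
        gamma=gamma, concentrations=conc, activities=act,
    )


# --- tabular I/O -----------------------------------------------------------

def media_from_csv(path) -> list[MediumComposition]:
    """Read media from CSV (columns: label, pH, temp_C, Ca_mM, Mg_mM, K_mM,
    Na_mM, Cl_mM, NO3_mM, SO4_mM, P_mM, As_uM, buffer_mM; missing -> 0)."""
    df = pd.read_csv(path)
    media = []
    for _, row in df.iterrows():
        totals = {}
        for col, (key, scale) in _CSV_COLUMNS.items():
            if col in df.columns and pd.notna(row[col]):
                totals[key] = float(row[col]) * scale
        media.append(MediumComposition(
            label=str(row.get("label", f"medium_{_}")),
            pH=float(row.get("pH", 7.0)),
            temperature=float(row["temp_C"]) if "temp_C" in df.columns and pd.notna(row.get("temp_C")) else 25.0,
            totals=totals,
            buffer_concentration=float(row["buffer_mM"]) * 1e-3
            if "buffer_mM" in df.columns and pd.notna(row.get("buffer_mM")) else 0.0,
        ))
    return media


def media_to_csv(media: list[MediumComposition], path) -> None:
    rows = []
    for m in media:
        row = {"label": m.label, "pH": m.pH, "temp_C": m.temperature,
               "buffer_mM": m.buffer_concentration * 1e3}
        for col, (key, scale) in _CSV_COLUMNS.items():
            row[col] = m.total(key) / scale
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def speciation_to_frame(results: list[SpeciationResult]) -> pd.DataFrame:
    """Long-format table: label, ionic_strength_M, species, charge,
    concentration_M, activity_M."""
    rows = []
    for r in results:
        for species, conc in r.concentrations.items():
            rows.append({
                "label": r.label,
                "ionic_strength_M": r.ionic_strength,
                "species": species,
                "charge": SPECIES_CHARGE.get(species, 0),
                "concentration_M": conc,
                "activity_M": r.activities.get(species, conc),
            })
    return pd.DataFrame(rows)
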