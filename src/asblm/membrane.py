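"""Gouy-Chapman-Stern model of the root-cell plasma-membrane surface.

The membrane carries negatively charged sites R- and neutral sites P0 to
which cations bind (Stern layer); the resulting surface charge density
sigma must simultaneously satisfy the Graham equation for the diffuse
double layer.  The surface electrical potential psi0 is the value at which
the two sigma expressions agree.

Sign conventions: psi0 is in volts internally (reported in mV); a
negatively charged membrane has sigma < 0 and psi0 < 0, so the Graham
square root is assigned the sign of psi0.  Bulk inputs to the Graham and
Boltzmann equations are free-ion *concentrations*: the diffuse-layer sum
requires an electroneutral ion set, which single-ion activities are not.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.optimize import brentq

from .constants import FARADAY, GRAHAM_COEFF, R_GAS, SPECIES_CHARGE, T_KELVIN
from .speciation import SpeciationResult

__all__ = [
    "MembraneParams",
    "MembraneState",
    "graham_sigma",
    "boltzmann_surface",
    "binding_sigma",
    "solve_psi0",
    "default_membrane_params",
]

#: Bracket for the psi0 search (V).
PSI0_BRACKET = (-0.3, 0.1)
#: Convergence tolerance on |sigma_graham - sigma_binding| (C/m^2).
SIGMA_TOL = 1e-9
#: Reject bulk psi0 magnitudes beyond this (exp overflow guard).
PSI0_MAX = 0.5


@dataclass(frozen=True)
class MembraneParams:
    """Stern-layer site densities and cation binding constants.

    ``r_total``/``p_total`` are the surface densities (mol/m^2) of the
    negatively charged (R-) and neutral (P0) binding sites.  ``k_r`` and
    ``k_p`` map cation species names to conditional binding constants
    (L/mol) for R- + I^Z <-> RI^(Z-1) and P0 + I^Z <-> PI^Z.
    """

    r_total: float
    p_total: float
    k_r: dict[str, float] = field(default_factory=dict)
    k_p: dict[str, float] = field(default_factory=dict)
    source_label: str = ""

    def __post_init__(self) -> None:
        if self.r_total < 0 or self.p_total < 0:
            raise ValueError("site densities must be >= 0")
        for kmap in (self.k_r, self.k_p):
            for ion, k in kmap.items():
                if k < 0:
                    raise ValueError(f"negative binding constant for {ion}")
                if SPECIES_CHARGE.get(ion, 0) <= 0:
                    raise ValueError(f"{ion}: only cations bind R-/P0 sites")

    @classmethod
    def from_yaml(cls, path) -> "MembraneParams":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls._from_mapping(raw)

    @classmethod
    def _from_mapping(cls, raw: dict) -> "MembraneParams":
        k_r, k_p = {}, {}
        r_total = p_total = 0.0
        for site in raw["sites"]:
            density = float(site["density_umol_m2"]) * 1e-6
            kmap = {ion: 10.0 ** float(logk) for ion, logk in site.get("logK", {}).items()}
            if site["site"] == "R":
                r_total, k_r = density, kmap
            elif site["site"] == "P":
                p_total, k_p = density, kmap
            else:
                raise ValueError(f"unknown site type {site['site']!r}")
        return cls(r_total=r_total, p_total=p_total, k_r=k_r, k_p=k_p,
                   source_label=raw.get("source", ""))


@dataclass
class MembraneState:
    """Converged surface state: potential, charge density, surface phase."""

    label: str
    psi0: float  # V
    sigma: float  # C/m^2
    residual: float  # C/m^2
    converged: bool
    surface_activities: dict[str, float]
    surface_concentrations: dict[str, float]

    @property
    def psi0_mV(self) -> float:
        return self.psi0 * 1e3


def default_membrane_params() -> MembraneParams:
    """Vendored plant plasma-membrane parameter set (see data/membrane_plant.yaml)."""
    ref = importlib.resources.files("asblm.data") / "membrane_plant.yaml"
    with importlib.resources.as_file(ref) as path:
        return MembraneParams.from_yaml(path)


def _thermal_voltage(T: float = T_KELVIN) -> float:
    return R_GAS * T / FARADAY


def graham_sigma(psi0: float, bulk: SpeciationResult, T: float = T_KELVIN) -> float:
    """Diffuse-layer surface charge density from the Graham equation.

    sigma^2 = 0.00345 * sum_i c_i (exp(-z_i F psi0 / RT) - 1) with c_i the
    bulk free-ion concentrations in mol/L; the root is given the sign of
    psi0 (negative potential <=> negative membrane charge).
    """
    if abs(psi0) > PSI0_MAX:
        raise ValueError(f"|psi0| = {abs(psi0):.3g} V exceeds {PSI0_MAX} V guard")
    vt = _thermal_voltage(T)
    total = 0.0
    for species, z in bulk.charged_species().items():
        c = bulk.concentration(species)
        total += c * np.expm1(-z * psi0 / vt)
    # Electroneutral solutions give total >= 0; clip rounding noise.
    total = max(total, 0.0)
    return float(np.sign(psi0) * np.sqrt(GRAHAM_COEFF * total))


def boltzmann_surface(bulk_value: float, charge: int, psi0: float,
                      T: float = T_KELVIN) -> float:
    """Surface-phase value of a bulk quantity: bulk * exp(-z F psi0 / RT)."""
    if charge == 0:
        return bulk_value
    return float(bulk_value * np.exp(-charge * psi0 / _thermal_voltage(T)))


def binding_sigma(psi0: float, bulk: SpeciationResult, params: MembraneParams,
                  T: float = T_KELVIN) -> float:
    """Stern-layer surface charge density from cation binding.

    Surface-local cation concentrations follow the Boltzmann factor; the two
    site mass balances are linear in the free site densities, giving
    sigma = F * (-[R-] + sum (z-1)[RI^(z-1)] + sum z [PI^z]).
    """
    surf = {ion: boltzmann_surface(bulk.concentration(ion), SPECIES_CHARGE[ion], psi0, T)
            for ion in set(params.k_r) | set(params.k_p)}
    r_denom = 1.0 + sum(k * surf[ion] for ion, k in params.k_r.items())
    p_denom = 1.0 + sum(k * surf[ion] for ion, k in params.k_p.items())
    r_free = params.r_total / r_denom
    p_free = params.p_total / p_denom
    sigma_mol = -r_free
    for ion, k in params.k_r.items():
        sigma_mol += (SPECIES_CHARGE[ion] - 1) * k * surf[ion] * r_free
    for ion, k in params.k_p.items():
        sigma_mol += SPECIES_CHARGE[ion] * k * surf[ion] * p_free
    return float(sigma_mol * FARADAY)


def solve_psi0(bulk: SpeciationResult, params: MembraneParams,
               T: float = T_KELVIN,
               bracket: tuple[float, float] = PSI0_BRACKET) -> MembraneState:
    """Find psi0 where the Graham and Stern charge densities agree.

    Bracketed Brent root-finding on the residual sigma_graham - sigma_binding;
    deterministic and initial-guess free.  Raises if the bracket contains no
    sign change (never returns an unconverged state silently).
    """

    def residual(psi: float) -> float:
        return graham_sigma(psi, bulk, T) - binding_sigma(psi, bulk, params, T)

    lo, hi = bracket
    f_lo, f_hi = residual(lo), residual(hi)
    if f_lo == 0.0:
        root = lo
    elif f_hi == 0.0:
        root = hi
    elif f_lo * f_hi > 0:
        raise RuntimeError(
            f"no sign change for psi0 in [{lo}, {hi}] V for medium "
            f"{bulk.label!r}: residual({lo}) = {f_lo:.3g}, "
            f"residual({hi}) = {f_hi:.3g} C/m^2"
        )
    else:
        root = brentq(residual, lo, hi, xtol=1e-12, rtol=8.9e-16, maxiter=200)
    res = residual(root)
    surf_c = {sp: boltzmann_surface(bulk.concentration(sp), z, root, T)
              for sp, z in SPECIES_CHARGE.items() if sp in bulk.concentrations}
    surf_a = {sp: boltzmann_surface(bulk.activity(sp), SPECIES_CHARGE.get(sp, 0), root, T)
              for sp in bulk.activities}
    return MembraneState(
        label=bulk.label,
        psi0=float(root),
        sigma=graham_sigma(root, bulk, T),
        residual=float(res),
        converged=abs(res) < SIGMA_TOL,
        surface_activities=surf_a,
        surface_concentrations=surf_c,
    )
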