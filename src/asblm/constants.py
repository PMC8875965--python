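"""Physical constants, equilibrium constants and published model parameters.

All equilibrium constants are 25 degC values and are used at 25 degC
throughout: the lumped Graham-equation coefficient (0.00345) is itself a
25 degC value, so mixing in 20 degC acidity constants would be less
consistent, not more.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import MappingProxyType

# --- fundamental constants -------------------------------------------------

FARADAY = 96485.332  # C/mol
R_GAS = 8.31446  # J/(mol K)
T_KELVIN = 298.15  # K; all equilibrium data are 25 degC values

#: Lumped 2*eps_r*eps0*R*T for the Graham equation, giving sigma in C/m^2
#: when bulk concentrations are in mol/L (25 degC, water).
GRAHAM_COEFF = 0.00345

# Davies single-ion activity model, Debye-Hueckel slope at 25 degC.
DAVIES_A = 0.509
DAVIES_B = 0.3
DAVIES_I_LIMIT = 0.5  # mol/L; above this the model is extrapolating

PKW = 14.0  # water autoprotolysis, 25 degC

# --- acid-base chemistry ---------------------------------------------------

#: Stepwise pKa of arsenic acid H3AsO4. Step 2 (H2AsO4-/HAsO42-) is the
#: conditional value used by the A. fischeri arsenate BLM (pK_As = 6.76);
#: steps 1 and 3 are the critically compiled values (Nordstrom & Archer,
#: 2003: 2.26, 11.29 at 25 degC).
PKA_ARSENATE = (2.26, 6.76, 11.29)

#: Stepwise pKa of phosphoric acid H3PO4 (CRC/IUPAC critical values, 25 degC).
PKA_PHOSPHATE = (2.148, 7.198, 12.35)

# --- species table ---------------------------------------------------------

#: Charge of every species the speciation module reports.
SPECIES_CHARGE: MappingProxyType[str, int] = MappingProxyType({
    "H+": 1, "OH-": -1,
    "Ca2+": 2, "Mg2+": 2, "K+": 1, "Na+": 1,
    "Cl-": -1, "NO3-": -1, "SO42-": -2,
    "H3AsO4": 0, "H2AsO4-": -1, "HAsO42-": -2, "AsO43-": -3,
    "H3PO4": 0, "H2PO4-": -1, "HPO42-": -2, "PO43-": -3,
})

ARSENATE_SPECIES = ("H3AsO4", "H2AsO4-", "HAsO42-", "AsO43-")
PHOSPHATE_SPECIES = ("H3PO4", "H2PO4-", "HPO42-", "PO43-")

#: Fully dissociated major ions: medium total -> free species name.
MAJOR_IONS: MappingProxyType[str, str] = MappingProxyType({
    "Ca": "Ca2+", "Mg": "Mg2+", "K": "K+", "Na": "Na+",
    "Cl": "Cl-", "NO3": "NO3-", "SO4": "SO42-",
})

# --- biotic ligand model constants (A. fischeri calibration) ---------------


@dataclass(frozen=True)
class BLMConstants:
    """Conditional binding constants of the arsenate biotic ligand model.

    The active binding site X binds the two arsenate species present at
    circumneutral pH and the two competing phosphate species; constants are
    conditional (L/mol) and were fitted on *Aliivibrio fischeri*
    bioluminescence data.  ``pK_As`` is the conditional H2AsO4-/HAsO42-
    acidity constant the model uses to tie the two arsenate activities
    together.
    """

    logK_XH2AsO4: float = 3.067
    logK_XHAsO4: float = 4.802
    logK_XH2PO4: float = 3.424
    logK_XHPO4: float = 4.588
    pK_As: float = 6.76

    @property
    def K_XH2AsO4(self) -> float:
        return 10.0 ** self.logK_XH2AsO4

    @property
    def K_XHAsO4(self) -> float:
        return 10.0 ** self.logK_XHAsO4

    @property
    def K_XH2PO4(self) -> float:
        return 10.0 ** self.logK_XH2PO4

    @property
    def K_XHPO4(self) -> float:
        return 10.0 ** self.logK_XHPO4

    @property
    def K_As(self) -> float:
        return 10.0 ** (-self.pK_As)


#: Inherent sensitivity registry: species -> (endpoint, f_mix50).
#: f_mix50 is the fraction of active binding sites occupied by arsenate
#: at 50% effect; IS = f/(1-f).
SENSITIVITY_REGISTRY = MappingProxyType({
    "A. fischeri": ("5 min bioluminescence inhibition", 0.616),
    "H. vulgare": ("5 d relative root elongation", 0.626),
    "T. aestivum": ("2 d relative root elongation", 0.015),
})

#: Published psi0-EC50 linear fits (slope in uM per mV, intercept-free
#: registry: the underlying per-Ca EC50 points were published only
#: graphically, so the slopes are consumed as constants, never re-derived).
PUBLISHED_PSI0_FITS = MappingProxyType({
    "H. vulgare": {"slope_uM_per_mV": -0.615, "r_squared": 0.771},
    "T. aestivum": {"slope_uM_per_mV": -0.003, "r_squared": 0.729},
    "normalized": {"slope_per_mV": -0.055, "r_squared": 0.742},
})

#: Measured barley EC50 anchors (HAsO4 2- activity, mol/L) from the
#:  hydroponic root-elongation study: Ca ladder endpoints.
MEASURED_EC50_HVULGARE = MappingProxyType({
    0.2e-3: (45.1e-6, 4.34e-6),   # Ca total (M) -> (EC50, sd)
    20e-3: (15.0e-6, 2.60e-6),
})

DEFAULT_BLM_CONSTANTS = BLMConstants()
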