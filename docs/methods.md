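# Methods

This note records the models implemented in `asblm`, the parameter choices
that matter, and what the tests do and do not demonstrate.

## Chemical speciation

Media are defined by total dissolved concentrations (Ca, Mg, K, Na, Cl,
NO₃, SO₄, total orthophosphate, total As(V)), pH and temperature. The MOPS
buffer is treated as chemically inert and excluded from ionic strength: at
pH 7 it is predominantly zwitterionic and carries no net charge.

Single-ion activity coefficients use the Davies equation
(log₁₀γ = −0.509 z² (√I/(1+√I) − 0.3 I), 25 °C). Arsenate and phosphate
are distributed over their protonation states by mass action with
activity-based constants; major ions are treated as fully dissociated.
Ionic strength is evaluated on a first pass at γ = 1 and the activity
coefficients are then re-evaluated on the speciated concentrations in a
fixed two-cycle iteration (a third cycle moves the distribution by less
than 0.1% at these ionic strengths).

Acidity constants (25 °C): arsenic acid pKa 2.26 / **6.76** / 11.29 —
step 2 is the conditional value used by the arsenate BLM, deliberately
overriding the thermodynamic compilation value so the speciation and the
BLM share one constant; phosphoric acid pKa 2.148 / 7.198 / 12.35
(critical compilation values).

Deliberate omissions, as package-level simplifications relative to a full
thermodynamic-database code: ion pairing (CaHPO₄⁰, CaSO₄⁰, NaHAsO₄⁻, …),
the carbonate system, redox chemistry and temperature corrections (all
constants are used at 25 °C, matching the lumped Graham coefficient). At
the study's ionic strengths the ion-pair effect on the phosphate activities
is on the order of a few percent; this is the main reason the computed
environmental modulator (2.72 × 10⁻⁵ M for the background medium) sits ~1%
above the reference value computed with a full database (2.70 × 10⁻⁵ M).

Charge balance: builders close the charge balance by topping up Cl⁻ or Na⁺
(emulating the acid/base used for pH adjustment and the counter-ions of
added salts; As(V) doses carry 2 Na⁺ per As as the disodium salt). The
closure is iterated to numerical neutrality because the Gouy–Chapman sum
is only non-negative for an electroneutral ion set. Above I = 0.5 M the
Davies model is extrapolating; the package warns and proceeds.

## Gouy–Chapman–Stern membrane model

The plasma-membrane surface carries negatively charged sites R⁻ and
neutral sites P⁰. Cations I^Z bind both (R⁻ + I^Z ⇌ RI^(Z−1), K_RI;
P⁰ + I^Z ⇌ PI^Z, K_PI) at surface-local concentrations given by the
Boltzmann factor exp(−zFΨ₀/RT). The Stern surface charge density
σ = F(−[R⁻] + Σ(z−1)[RI] + Σz[PI]) must equal the diffuse-layer charge
from the Graham equation, σ² = 0.00345 Σ cᵢ(exp(−zᵢFΨ₀/RT) − 1) with
concentrations in mol/L (the coefficient lumps 2εᵣε₀RT at 25 °C and the
unit conversion). Ψ₀ is located by bracketed Brent root-finding on
σ_Graham − σ_Stern over [−0.3, +0.1] V (xtol 10⁻¹² V); every solve asserts
a fixed-point residual below 10⁻⁹ C/m² and a failed bracket raises rather
than returning an unconverged value.

**Concentrations, not activities.** The Graham and Boltzmann equations are
fed free-ion *concentrations*. Feeding single-ion activities breaks the
electroneutrality on which the Graham sum relies (γ for divalent cations
falls much faster than for monovalent anions, so the activity-weighted sum
can go negative near Ψ₀ = 0 in high-Ca media and the root disappears);
with concentrations the sum is non-negative by construction.

**Parameter provenance.** The site densities and binding constants follow
the classical plant-membrane electrostatics literature in structure
(R_T = 0.3074 µmol/m², P_T = 2.4 µmol/m², K_R(H⁺) = 21 380 L/mol,
monovalent cations near 1 L/mol). The four cation constants that the
published anchor potentials actually constrain — Ca²⁺/Mg²⁺ and Na⁺/K⁺ on
each site type — were calibrated once against the four published Ψ₀
anchors (plant background medium at 0.2 / 20 mM Ca²⁺: −53.8 / −3.3 mV;
0.342 M NaCl assay medium at 0 / 25 mM Ca²⁺: −13.7 / −0.4 mV), rounded to
three decimals in log K, and frozen in `data/membrane_plant.yaml`
(log K_R(Ca) = 1.444, log K_R(Na) = −0.068, log K_P(Ca) = −0.616,
log K_P(Na) = −2.053). Each anchor is reproduced to better than 0.01 mV.
The same parameter set is applied to both organisms — the anchor data are
only consistent with a shared GCS machinery — and this is an assumption,
not a result. Arsenate and phosphate oxyanions interact with the surface
only electrostatically (no Stern binding), consistent with attributing
their surface accumulation purely to Ψ₀.

## Biotic ligand model and extrapolation

Conditional binding constants (L/mol, from the *A. fischeri* arsenate BLM):
log K_XH₂AsO₄ = 3.067, log K_XHAsO₄ = 4.802, log K_XH₂PO₄ = 3.424,
log K_XHPO₄ = 4.588; pK_As = 6.76. These are treated as transferable
across species; the only per-species quantity is the inherent sensitivity
IS = f₅₀/(1−f₅₀), calibrated from a single measured EC50 and the
test-medium EM (registry values: *A. fischeri* 0.616, *H. vulgare* 0.626,
*T. aestivum* 0.015).

The Ψ₀ correction is linear, EC50_site = EC50_ini + p(Ψ₀,site − Ψ₀,ini),
with p in µM/mV. Published slopes (−0.615 µM/mV for barley, −0.003 µM/mV
for wheat, and −0.055 /mV for the intercept-normalised common relation)
ship as read-only constants: the per-calcium EC50 points behind those
regressions were published only graphically, so the package consumes the
slopes and checks only two-point consistency (the printed ladder endpoints
give −0.596 µM/mV). Outside the linear range the correction can cross
zero; the package floors the result at 1% of the uncorrected value with a
warning (configurable, or an error with flooring disabled). Normalising an
EC50 by the fitted intercept (EC50 at Ψ₀ = 0) removes species sensitivity
and exposes the common electrostatic slope; this normalised-slope route to
p for unseen species is exposed but labelled an extension.

All model EC50s are HAsO₄²⁻ activities (mol/L internally; µM in the slope
interface, enforced by the function signatures).

## Dose–response stage

Relative root elongation is computed from per-treatment mean elongations
against the control mean; the control is 100% by construction. The
four-parameter logistic y = y₀ + a/(1 + e^(−(x−x₀)/b)) is fitted by
Levenberg–Marquardt on per-treatment means (matching the endpoint's
definition on averages), with the deterministic start y₀ = min y,
a = range y, x₀ = median x, |b| = range x / 6 signed by the observed
trend. EC50 is defined as the crossing of y = 50 — absolute percent of
control, not the curve midpoint; the two coincide for a full-range 0–100
curve, and the tests assert this. Uncertainty is a parametric bootstrap
(default 1000 draws from the asymptotic parameter covariance, fixed seed)
on the 50% crossing; draws whose curve never crosses 50% are dropped. A
fit that does not converge is flagged and refuses to yield an EC50.

## Synthetic-data generator

The generator emulates the hydroponic root-elongation design: a Ca²⁺
ladder (0.2, 1, 5, 10, 20 mM) over the fixed background medium, seven
As(V) treatments (0, 0.5, 2, 10, 50, 200, 1000 µM) with six seeds each.
For each Ca level it computes Ψ₀ and a true EC50 (IS × EM baseline plus
the linear Ψ₀ shift relative to the lowest-Ca medium, so generator and
estimator share one forward model — the circularity is intentional: the
round trip tests the code, not the biology). Expected RRE follows the
logistic truth with b = −0.7 in ln-activity units; per-seed elongations
get additive Gaussian noise scaled to 5% of the control elongation
(truncated at 0 mm), around a control elongation of 60 ± 6 mm and initial
lengths of 10 ± 1 mm — values chosen at the scale typical of 5-day barley
seedlings, since no error model or length scale is part of the published
design. Output is byte-deterministic for a fixed seed.

What passing recovery tests show: the estimation chain inverts the forward
model within its noise budget (median f₅₀ error ≪ 0.05, median EC50 error
≪ 10% across 200 replicates). What they do not show: anything about real
seed-to-seed biology (no heteroscedasticity, no hormesis, no germination
failures, no between-beaker effects), and the recovered Ψ₀–EC50 slope
estimates the slope of the generator's truth points — which bundles the EM
drift across the ladder with the Ψ₀ shift (≈ −0.73 µM/mV at the default
settings) — not the injected p alone.

## Numerical choices and degenerate inputs

- Ψ₀ bracket [−0.3, +0.1] V; |Ψ₀| > 0.5 V rejected before exponentiation.
- Zero site densities give σ ≡ 0 and Ψ₀ = 0 exactly; an empty binding map
  with R_T > 0 is a valid fully deprotonated surface.
- speciation mass balance is exact by construction (fraction
  normalisation); property-tested to 10⁻⁶ relative.
- Dose–response fits require ≥ 5 distinct exposures and a non-constant
  response; EC50 extraction requires the fitted curve to cross 50%.
- The Davies γ(I) curve turns upward near I ≈ 0.39 mol/L; monotonicity is
  only asserted below that.

## Problem sizes

The test suite and the reference scripts run at the study's own scale:
5-medium ladders, 7 × 6 toxicity tables, 200-replicate recovery sweeps,
50-medium property scans with a 0.01 mV brute-force grid oracle — a few
seconds each on one core.

## Known limitations

- The speciation is a deliberate simplification of a database code; EM
  values carry a few percent of model error (covered by the stated 10%
  tolerance).
- The membrane parameter set is anchored to four published potentials;
  media far outside the calibration envelope (exotic ion mixtures, pH far
  from 7) extrapolate both the binding constants and the Davies model.
- The Ψ₀–EC50 correction is linear and species-calibrated; it has no
  mechanistic saturation and must be floored at extreme depolarisation.
- Interspecies extrapolation transfers binding constants from a bacterium
  to plants; the package reproduces the published order-of-magnitude
  agreement, not better.
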