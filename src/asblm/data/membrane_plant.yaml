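# Plant plasma-membrane Gouy-Chapman-Stern parameter set.
#
# Structure and fixed values follow the Kinraide-family PM surface model
# (negatively charged R- sites plus neutral P0 sites; R_T = 0.3074,
# P_T = 2.4 umol/m2; K_R(H+) = 21380 L/mol).  The remaining cation binding
# constants were calibrated once against the four published psi0 anchors for
# this model (plant background medium at 0.2 / 20 mM Ca: -53.8 / -3.3 mV;
# 0.342 M NaCl assay medium at 0 / 25 mM Ca: -13.7 / -0.4 mV) and then
# frozen; each anchor is reproduced to better than 0.01 mV.
# The same set is applied to both organisms (shared GCS machinery).
source: "Kinraide-family PM site model, cation logK calibrated to the four published psi0 anchors"
sites:
  - site: R            # negatively charged sites, R- + I^Z <-> RI^(Z-1)
    density_umol_m2: 0.3074
    logK:
      "H+": 4.330      # 21380 L/mol, fixed
      "Ca2+": 1.444
      "Mg2+": 1.444
      "Na+": -0.068
      "K+": -0.068
  - site: P            # neutral sites, P0 + I^Z <-> PI^Z
    density_umol_m2: 2.4
    logK:
      "Ca2+": -0.616
      "Mg2+": -0.616
      "Na+": -2.053
      "K+": -2.053
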