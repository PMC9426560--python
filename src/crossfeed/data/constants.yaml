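# Physicochemical constants and bundled kinetic parameter sets.
# Schema version bumps when field names change.
version: 1

acids:
  acetic:
    pKa: 4.76
    molar_mass: 60.0          # g/mol
    combustion_enthalpy: 875.0  # kJ/mol
    formula: {C: 2, H: 4, O: 2}
  lactic:
    pKa: 3.86
    molar_mass: 90.0
    combustion_enthalpy: 1362.0
    formula: {C: 3, H: 6, O: 3}

media:
  # Low-phosphate modified M9: 0.9 g/L Na2HPO4 only (6.3 mM total phosphate),
  # a weakly buffered medium.  Conventional M9 carries 64 mM total phosphate.
  low_phosphate:
    phosphate_total: 6.3      # mM
    phosphate_pKa2: 7.20
    initial_pH: 7.0
    glucose_0: 27.77777777777778   # mM  (5 g/L glucose)
    acid_0: 0.0
  conventional:
    phosphate_total: 64.0
    phosphate_pKa2: 7.20
    initial_pH: 7.0
    glucose_0: 27.77777777777778
    acid_0: 0.0

# Wild-type dose-response model parameterizations (specific growth rate laws).
# Concentration basis for every organic-acid variable is the PROTONATED
# species (HA), in mM; H is mol/L.
inhibition_models:
  acetic_sole:
    form_id: monod_haldane_exp
    params: {mu_max: 0.4, ks: 0.0723, ki: 0.760}
  lactic_sole:
    form_id: monod_haldane_exp
    params: {mu_max: 0.5, ks: 0.0038, ki: 0.317}
  acetic_glucose:
    form_id: monod_product_exp
    params: {mu_max: 0.65, kg: 0.005, k: 1.35}
  lactic_glucose:
    form_id: dual_substrate_exp
    params: {mu_max: 0.65, kg: 0.005, kl: 0.0743, alpha: 4.44}
  ph:
    form_id: linear_pH
    params: {mu_max: 0.665, h_star: 3.9810717055349695e-05}  # 10^-4.4 M
  combined_acetic:
    form_id: combined_stress
    params: {mu_max: 0.65, kg: 0.005, k: 1.35, h_star: 3.9810717055349695e-05}

# Ghose-Tyagi critical product concentrations (protonated acid, mM) used by
# the producer rate laws in the batch simulator.
ghose_tyagi_pstar:
  acetic: 1.44
  lactic: 0.45
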