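# Glyphosate in Isfahan drinking water: built-in case-study scenario.
# Concentrations in ug/L; exposure factors in the units of the intake
# equation (IR L/d, EF d/yr, ED yr, BW kg, AT d, RfD mg/kg-day).
schema_version: 1
metadata:
  study: Glyphosate drinking-water hazard assessment
  site: Isfahan, Iran (Zayanderud River and urban wells)
  notes: Water-quality fields are carried as metadata only; they enter no computation.
contaminant:
  name: glyphosate
  reference_dose: 0.1
water_sources:
  surface:
    concentration: {mean: 1.32, sd: 0.13}
    water_quality:
      pH: 7.56
      dissolved_oxygen_mgL: 6.22
      electrical_conductivity_uScm: 136.92
      nitrate_mgL_as_N: 1.0
      total_hardness_mgL: 151.4
      total_alkalinity_mgL: 147.2
  ground:
    concentration: {mean: 0.69, sd: 0.17}
    water_quality:
      pH: 6.97
      dissolved_oxygen_mgL: 2.97
      electrical_conductivity_uScm: 459.0
      nitrate_mgL_as_N: 0.58
      total_hardness_mgL: 229.67
      total_alkalinity_mgL: 100.33
deterministic_factors:
  children: {IR: 0.78, EF: 350, ED: 4, BW: 15, AT: 1400}
  teens: {IR: 2.0, EF: 350, ED: 13, BW: 50, AT: 4550}
  adults: {IR: 2.5, EF: 350, ED: 40, BW: 80, AT: 14000}
probabilistic_specs:
  children:
    IR: {kind: lognormal, mean: 0.51, sd: 0.14}
    EF: {kind: fixed, value: 365}
    ED: {kind: uniform, low: 1, high: 7}
    BW: {kind: lognormal, mean: 16.41, sd: 3.78}
    AT: {kind: fixed, value: 1400}
    RfD: {kind: fixed, value: 0.1}
  teens:
    IR: {kind: lognormal, mean: 1.12, sd: 0.27}
    EF: {kind: fixed, value: 365}
    ED: {kind: uniform, low: 8, high: 25}
    BW: {kind: lognormal, mean: 46.25, sd: 10.16}
    AT: {kind: fixed, value: 4550}
    RfD: {kind: fixed, value: 0.1}
  adults:
    IR: {kind: lognormal, mean: 1.23, sd: 0.27}
    EF: {kind: fixed, value: 365}
    ED: {kind: uniform, low: 26, high: 80}
    BW: {kind: lognormal, mean: 77.45, sd: 13.60}
    AT: {kind: fixed, value: 14000}
    RfD: {kind: fixed, value: 0.1}
simulation:
  iterations: 100000
  seed: 20220901
  convergence_tolerance: 0.01
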