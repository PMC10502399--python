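# hqrisk

Probabilistic human-health risk assessment for contaminants ingested via
drinking water: deterministic and Monte-Carlo hazard quotients, rank-
correlation sensitivity analysis and replicate-based convergence checking.
The package ships a complete case study — glyphosate in the surface water
and groundwater supplying Isfahan, Iran, assessed for children, teens and
adults — and accepts user scenarios from a validated YAML config.

It is aimed at environmental-health scientists and water-quality risk
assessors who want auditable, seeded, fully scripted assessments instead
of spreadsheet add-in workflows.

## The model

The chronic estimated daily intake through drinking water is

```
EDI = (C / 1000) · IR · EF · ED / (BW · AT)     [mg/kg-day]
```

with C the contaminant concentration (µg/L; the division by 1000 converts
to mg/L exactly once), IR the water ingestion rate (L/d), EF the exposure
frequency (d/yr), ED the exposure duration (yr), BW body weight (kg) and
AT the averaging time (d). Non-carcinogenic risk is characterized by the
hazard quotient

```
HQ = EDI / RfD
```

against an oral reference dose RfD (mg/kg-day); HQ < 1 means adverse
effects are not anticipated.

The deterministic assessment evaluates these with point values per
population group. The probabilistic assessment replaces them with
distributions (lognormal IR and BW parameterized by arithmetic mean/SD,
uniform ED, zero-truncated normal concentrations, fixed EF/AT/RfD) and
propagates 100,000 Monte-Carlo iterations through the same arithmetic.
Output uncertainty is attributed to inputs by Spearman rank correlation,
normalized to signed contribution-to-variance percentages
`sign(ρᵢ)·100·ρᵢ²/Σρⱼ²`; convergence is verified by comparing mean,
median and 95th percentile between two independently seeded replicates.

## Worked example

```python
import hqrisk as hq

config = hq.builtin_glyphosate_scenario()

# point estimates for all six cells
for (group, source), r in hq.deterministic_assessment(config.exposure_scenarios()).items():
    print(f"{group:9s} {source:8s} EDI={r.edi:.3e} mg/kg-day  HQ={r.hq:.3e}")

# probabilistic assessment for children drinking surface water
scenario = config.probabilistic_scenario("children", "surface")
sim = hq.run_simulation(scenario, iterations=100_000, stream=hq.RandomStream(42))
s = sim.summary
print(f"mean HQ={s.mean:.3e}  sd={s.sd:.3e}  p5={s.p5:.3e}  p95={s.p95:.3e}")

for rec in hq.sensitivity_analysis(sim).records:
    print(f"{rec.name:3s} rho={rec.rho:+.3f}  contribution={rec.contribution_pct:+.1f}%")
```

prints

```
children  surface  EDI=6.864e-05 mg/kg-day  HQ=6.864e-04
children  ground   EDI=3.588e-05 mg/kg-day  HQ=3.588e-04
teens     surface  EDI=5.280e-05 mg/kg-day  HQ=5.280e-04
teens     ground   EDI=2.760e-05 mg/kg-day  HQ=2.760e-04
adults    surface  EDI=4.125e-05 mg/kg-day  HQ=4.125e-04
adults    ground   EDI=2.156e-05 mg/kg-day  HQ=2.156e-04
mean HQ=4.512e-04  sd=2.708e-04  p5=1.212e-04  p95=9.634e-04
ED  rho=+0.796  contribution=+66.7%
IR  rho=+0.416  contribution=+18.2%
BW  rho=-0.347  contribution=-12.7%
Ci  rho=+0.153  contribution=+2.5%
```

Every hazard quotient sits three orders of magnitude below 1 — no adverse
effects anticipated — with children the most exposed group in both
sources, and exposure duration (ED) by far the dominant driver of output
uncertainty.

## Command line

```sh
hqrisk demo                      # built-in scenario end-to-end, full report
hqrisk deterministic --config my_scenario.yaml
hqrisk simulate --config my_scenario.yaml --iterations 100000 --seed 7 \
    --out results --formats csv,json,png
hqrisk sensitivity --config my_scenario.yaml
```

Reports include a deterministic-vs-probabilistic bar chart, per-cell HQ
histograms (50 bins), tornado-style sensitivity charts, CSV tables and a
JSON master document carrying full provenance (seed, iterations, config
hash) so that every number is recomputable.

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
reruns the packaged glyphosate scenario from scratch and writes the
maximum deterministic HQ over the six (group × source) cells and the
maximum simulated mean HQ from 100,000-iteration Monte-Carlo runs, with
all randomness derived from `--seed`.

See `docs/methods.md` for modelling assumptions, parameter conventions
and known limitations.
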