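# Methods

## Model

The toolkit assesses chronic non-carcinogenic risk from oral ingestion of
a contaminant in drinking water. For one population group and one water
source the estimated daily intake is

    EDI = (C / 1000) · IR · EF · ED / (BW · AT)    [mg/kg-day]

and the hazard quotient is HQ = EDI / RfD. Concentrations are stored in
µg/L throughout and divided by 1000 exactly once, inside `compute_edi`;
this is the single unit-conversion point in the code (an optional flag
accepts pre-converted mg/L for round-trip checking). HQ < 1 is read as
"adverse effects not anticipated".

Assumptions: a single contaminant and the oral route only (no dermal or
inhalation pathways, no hazard-index summation across chemicals, no
carcinogenic slope factors); model inputs are mutually independent in the
probabilistic assessment.

## Parameters of the packaged scenario

Deterministic factors (per group: children / teens / adults):
IR 0.78 / 2 / 2.5 L/d, EF 350 d/yr, ED 4 / 13 / 40 yr, BW 15 / 50 / 80 kg,
AT 1400 / 4550 / 14000 d, RfD 0.1 mg/kg-day. Glyphosate concentrations:
surface 1.32 ± 0.13 µg/L, ground 0.69 ± 0.17 µg/L. Note that for every
group AT = EF × ED, so the deterministic EDI reduces to (C/1000)·IR/BW.

Probabilistic inputs: IR lognormal 0.51 ± 0.14 / 1.12 ± 0.27 /
1.23 ± 0.27 L/d; EF fixed 365 d/yr; ED uniform 1–7 / 8–25 / 26–80 yr;
BW lognormal 16.41 ± 3.78 / 46.25 ± 10.16 / 77.45 ± 13.60 kg; AT and RfD
fixed; concentrations normal with the per-source mean/SD. The
deterministic EF (350) and probabilistic EF (365) are deliberately kept
distinct: each table of the source study is reproduced as printed.

## Distribution conventions

- **Lognormal "mean ± SD"** is interpreted on the *arithmetic* scale and
  converted to the underlying normal by exact moment matching:
  σ² = ln(1 + (s/m)²), µ = ln(m) − σ²/2. This is the entry convention of
  the spreadsheet risk-analysis tools this workflow emulates; it is an
  explicit, overridable convention (`lognormal_underlying_params`).
- **Normal concentrations are truncated at zero** by rejection
  resampling: concentrations are physically non-negative and rejection
  preserves the distribution's shape better than clamping. The packaged
  means sit ≈10 SD (surface) and ≈4 SD (ground) above zero, so the
  truncation bias on the moments is ≲0.01%.
- **Uniform exposure durations are continuous** on the closed interval,
  not integer years.
- Sampling is plain Monte Carlo (no Latin hypercube or other variance
  reduction), using numpy's PCG64 generator.

## Averaging-time linkage

The probabilistic scenario keeps AT *fixed* per group while ED varies
uniformly, exactly as the source tables specify, even though this breaks
the AT = EF × ED linkage of the deterministic table and makes HQ linear
in ED. The consequence — ED dominating the sensitivity ranking (its
coefficient of variation, 0.43 / 0.30 / 0.29 across groups, exceeds every
other input's) — is reproduced, not corrected. For adults, ED ~ U(26, 80)
combined with AT = 14000 d means EF·ED/AT > 1 for most draws; this is
faithful to the published inputs and flagged here rather than altered.
`run_simulation(..., consistent_averaging_time=True)` offers the
conventional non-carcinogenic linkage AT = ED × 365 d as an opt-in mode
(off by default).

## Sensitivity measure

Spearman rank correlation (mid-ranks for ties, delegated to scipy)
between each stochastic input's draws and the HQ draws, normalized to
signed contribution-to-variance percentages sign(ρᵢ)·100·ρᵢ²/Σρⱼ².
Fixed inputs are excluded entirely — correlation with a constant is
undefined — rather than charted at 0%. The absolute contributions sum to
100% by construction.

## Numerical choices

- Summary statistics: mean, SD with n−1 denominator, median, 5th/95th
  percentiles by linear interpolation between order statistics (numpy's
  default, the common spreadsheet convention).
- Degenerate input rule: a constant draw vector summarizes exactly (mean,
  median and percentiles equal the constant, SD = 0), so an all-fixed
  scenario collapses bit-exactly onto the deterministic result, free of
  pairwise-summation rounding.
- Histograms: 50 equal-width bins spanning [min, max]; the source figures
  show histograms without stating bins, so this is a frozen artifact
  convention.
- Iterations default to 100,000. Convergence compares mean, median and
  p95 of two independently seeded replicates at a 1% relative tolerance
  (relative difference = |a−b| / pair mean). At 100,000 iterations the
  mean's relative standard error is ≈0.2%, comfortably inside tolerance;
  the p95's per-run spread is ≈0.4%, so the 1% tolerance is only a ≈2σ
  margin for that statistic and occasional non-convergence under fresh
  seed pairs is expected sampling behaviour, not a defect.
- Seeding: the default base seed 20220901 is recorded in every report.
  Each (group, source) cell simulates with
  `(base + crc32("group|source")) mod 2³¹`, so cells are independent and
  adding a cell never perturbs another's draws; convergence replicates
  add fixed large offsets to the cell seed.

## What the built-in scenario does and does not establish

The packaged case study is a *stated world*: measured concentration
summaries and literature exposure factors. Green tests establish that the
implementation reproduces the deterministic hand calculations exactly,
that sampled distributions recover their specified moments, that the
simulated mean matches the closed-form expectation under independence
(E[1/BW] taken from the lognormal reciprocal moment), and that the
qualitative findings — all HQ ≪ 1, children > teens > adults, ED
dominant — hold. They do not validate the exposure-factor values
themselves, the independence assumption, or any features of real
concentration time series (seasonality, detection limits, spatial
correlation) that a two-point mean ± SD summary cannot carry.

A note on deterministic-vs-probabilistic agreement: for children the
probabilistic mean HQ is ≈0.66× the point estimate, driven by the lower
probabilistic ingestion-rate mean (0.51 vs 0.78 L/d); the two approaches
agree within a factor of two for every cell, which is the level of
agreement the workflow claims.

## Limitations

- Single contaminant, single route; no aggregate or cumulative exposure.
- No correlated inputs and no distribution fitting from raw data; specs
  are declarative (fixed, normal, lognormal, uniform only).
- One-dimensional Monte Carlo: variability and knowledge uncertainty are
  not separated.
- Water-quality metadata (pH, dissolved oxygen, conductivity, nitrate,
  hardness, alkalinity) is carried into reports verbatim but never enters
  any computation.
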