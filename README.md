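# neoflux

Regional point-source emission estimation for neonicotinoid insecticides
(pNEOs) and their transformation products (mNEOs) in municipal wastewater.

Wastewater treatment plants (WWTPs) collect neonicotinoids from agricultural
runoff, industrial discharge and domestic use, remove only a fraction of
them, and release the rest into receiving waters as continuous point
sources. Quantifying those emissions at a regional scale is hard because
influent monitoring covers only a subset of plants and effluent data are
usually absent. `neoflux` implements a complete, tested pipeline for this
problem, aimed at environmental chemists and exposure modellers working with
plant registries and replicate-level influent monitoring tables:

- **Censoring-aware occurrence statistics** — values below the limit of
  quantification are set to zero (a conservative low-bound convention);
  detection frequencies, concentration summaries, composition profiles,
  land-use group contrasts (Welch *t*) and Pearson correlations all operate
  on plant means of replicates.
- **Parent/metabolite transformation ratios** (p/m-NEO), a proxy for
  pre-plant degradation, with exclusion of extreme outliers (ratio > 100)
  and zero denominators.
- **Literature removal-rate aggregation**: the removal rate of compound *j*
  at plant *i* is the unweighted mean of literature entry values for the
  plant's process class (ranges contribute their midpoint; UV-disinfection
  entries join the average where applied), metabolites inherit their
  parent's rate, and the plant rate is the mean over the parent panel:

  RR_i,j = mean(RR_mid-of-lit, RR_certain, …),  RR_i = (Σ_j RR_i,j)/n

- **Regression extrapolation**: class-total influent concentration is fit
  against served population (or designed capacity) by OLS with iterative
  Cook's-distance pruning toward R² ≥ 0.95; unsampled plants get the
  new-observation prediction interval

  ŷ ± t(α/2, n−2) · σ · √(1 + 1/n + (x − x̄)²/Sxx)

- **Mass-balance emission model**: annual effluent emission per plant and
  compound class

  E = Σᵢ Cᵢ · (1 − RRᵢ) · Vᵢ

  with C the influent concentration (ng/L) and V the annual discharge
  volume (10⁷ L), giving kg/a; plus derived loads, removed mass, removal
  percentages and plant shares.
- **Monte-Carlo uncertainty propagation** (100,000 iterations by default)
  over four independent sources — concentration (regression or measurement
  spread), removal-rate variability (uniform over literature bounds), flow
  error and analytical error — with per-plant substreams so results are
  reproducible and ordering-invariant, and one-at-a-time variance
  attribution.
- **Risk-quotient screening**: RQ = MEC/PNEC with four bands (negligible
  ≤ 0.1 < low < 1 ≤ moderate < 10 ≤ high).

A synthetic-data generator with a recorded ground truth emulates the survey
design the pipeline targets (21 sampled plants across 5 districts within a
larger region, 8 parents + 6 metabolites, concentrations linear in served
population with group offsets, lognormal replicates, LOD/LOQ censoring), so
every stage is testable end to end without any external data.

## Worked example

The numbered scripts under `analysis/` run the survey end to end against
the synthetic campaign (shared state in `results/survey/`):

```
$ python analysis/01_simulate.py 1
simulated 21 sampled plants of 60 in the region (seed 1)
concentration records: 1470 over 14 analytes

$ python analysis/06_emission_balance.py
parents: load 872.98 kg/a, emission 535.39 kg/a, removed 337.59 kg/a (38.67%)
metabolites: load 737.01 kg/a, emission 453.35 kg/a, removed 283.65 kg/a (38.49%)

$ python analysis/07_monte_carlo.py
parents city-wide: 538.38 +/- 31.54 kg/a (95% CI 479.83-603.23)
metabolites city-wide: 455.90 +/- 20.84 kg/a (95% CI 416.23-497.91)
parent-class variance attribution: {'concentration': '37%', 'removal': '25%',
                                    'flow': '15%', 'analytical': '23%'}
```

The first block is the deterministic mass balance over all 60 regional
plants (measured concentrations for the 21 sampled ones, regression
predictions elsewhere): of 872.98 kg of parent compounds entering plants per
year, 38.67% is removed in treatment and 535.39 kg is emitted to receiving
waters. The second block propagates the four uncertainty sources: the
city-wide parent emission is 538 ± 32 kg/a, with concentration uncertainty
the largest contributor. The same pipeline is available as a CLI
(`neoflux all --seed 1 --out results/run`) or programmatically via
`neoflux.pipeline.run_pipeline`.

Real data enter through four CSV schemas (plant registry, long-format
concentrations, literature removal rates, analyte definitions); see
`neoflux.core_data` docstrings. The bundled analyte panel carries synthetic
stand-in LOD/LOQ/PNEC values — supply your own for real assessments.

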