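# Methods

## Model overview

The pipeline estimates annual point-source emissions of neonicotinoid
parent compounds (pNEOs) and metabolites (mNEOs) from WWTP effluents using
influent monitoring data only. For plant *i* and compound class *j*,

    E_ij = C_ij · (1 − RR_i) · V_i · 10⁷ · 10⁻¹²   [kg/a]

where C_ij is the class-total influent concentration (ng/L), RR_i the
plant-mean removal fraction, and V_i the annual discharge volume in units
of 10⁷ L. Assumptions baked into this balance:

- influent and effluent volumes are equal (one V per plant);
- removal rates are literature-derived per treatment-process class, not
  measured in-plant;
- metabolite removal equals the parent compound's removal (no experimental
  mNEO removal data exist); in-plant transformation of parents *into*
  metabolites is not modelled, so metabolite emissions are, if anything,
  underestimated;
- concentrations below the quantification threshold are zero, making all
  loads and emissions conservative lower bounds.

## Censoring

One substitution rule is applied everywhere: a raw value below the
analyte's threshold becomes exactly 0. The threshold defaults to the LOQ
(config `censor_threshold: lod|loq`); the LOD/LOQ distinction collapses to
a single cutoff because LOQ ≥ LOD and the substitution is the same either
way. Non-detects may arrive as sentinel strings ("<LOD", "ND") or as
numerics below threshold. The rule is idempotent and monotone (property
tested). Plant-level values are replicate means; class totals are per-plant
sums of member-analyte means — every cross-plant statistic builds on these.

## Removal-rate aggregation

A literature entry is a point value or a range; ranges contribute their
midpoint. The (process class, analyte) rate is the unweighted mean of
matching entry values — no source-quality weights, since none are
defensible from typical literature compilations. Two process classes are
distinguished (AAO-like, covering AAO/SBR/Bardenpho trains, and oxidation
ditch). For plants with UV disinfection, UV entries for the analyte join
the averaging set (`uv_mode: append_average`, the default reading of
"also included"); serial composition 1−(1−a)(1−b) is available as
`uv_mode: serial` and gives systematically higher removal. The plant-level
rate is the unweighted mean over the parent panel — the per-plant reading
of the summation, which is what the emission model consumes. Missing
(process, analyte) cells are a hard error listing every gap; an opt-in
fallback to the process-class grand mean exists but is off by default.

## Regression extrapolation

Class totals are regressed on served population (default; designed
capacity selectable — population is the covariate the emission model's
generating structure names). Outliers are pruned iteratively: one point
per iteration, the largest Cook's distance first, ties broken
lexicographically by plant id, until R² ≥ `target_r2` (default 0.95) or
the retained set would fall below `min_n` = max(10, 60% of points). The
floor prevents pruning to a trivially collinear subset; hitting it below
target returns the fit flagged `below_target` with a warning rather than
an error, and under the default synthetic conditions (substantial land-use
group offsets and residual noise) that flag is the *expected* outcome for
the parent class — a reminder that a high post-pruning R² is a property of
the data, not a guarantee of the procedure. Predictions for unsampled
plants use the standard new-observation interval
ŷ ± t(α/2, n−2)·σ·√(1 + 1/n + (x−x̄)²/Sxx); its sd term feeds the
Monte-Carlo concentration spread, and predicted means are floored at 0
before entering the mass balance. Measured values always take precedence
over predictions for sampled plants.

## Monte-Carlo design

Four independent sources, sampled per iteration (defaults are declared
stand-ins, every one overridable in config):

| source | distribution | default spread |
|---|---|---|
| concentration | Normal(mean, sd), truncated at 0 | regression sd_pred, or SE of the measured mean |
| removal rate | Uniform(low, high) over literature entry bounds, clipped [0,1] | per-plant literature min–max |
| flow | multiplicative Normal(1, cv), truncated at 0 | cv = 0.10 |
| analytical | multiplicative Normal(1, cv), truncated at 0 | cv = 0.125 (typical method-recovery sd) |

Each (plant, class) cell draws from a substream keyed by the root seed and
a hash of the plant id, so per-plant summaries are bit-reproducible and
invariant to registry ordering; inactive sources still consume their draw
slot so one-at-a-time runs stay aligned. Regional totals are iteration-wise
sums of per-plant draws. Summaries are empirical mean, sd and percentile
CI (2.5/97.5 by default) — not a normal approximation. Variance attribution
re-runs one source at a time with the others degenerate and reports each
run's share of the summed variance; this is exact for independent additive
contributions and a good approximation for the small-cv multiplicative
terms used here. Truncation at zero biases a draw's mean upward when its
spread is comparable to its mean; the default flow/analytical cvs avoid
this, but the concentration term does not for small extrapolated plants
whose prediction sd rivals the predicted mean — there the Monte-Carlo mean
sits visibly above the deterministic balance, which is a property of the
declared truncated-normal input, not an error in the propagation (the
degenerate-spread collapse test pins the unbiased limit).

## Risk screening

RQ = MEC/PNEC per analyte, with MEC the across-plant mean concentration
(per-plant mode available). Bands: negligible RQ ≤ 0.1, low 0.1 < RQ < 1,
moderate 1 ≤ RQ < 10, high RQ ≥ 10 — the boundary at exactly 0.1 resolves
to negligible, making the bands disjoint. Analytes without a PNEC are
listed as not evaluable rather than banded.

## Synthetic-data generator

The generator defines the study conditions the tests and the acceptance
script run under: 21 sampled plants of a 60-plant region across 5
districts; designed capacities log-uniform over 912.5–73,000 thousand t/a;
served population proportional to capacity (≈8.3 persons per thousand t/a,
the survey-wide ratio) with 15% lognormal noise; discharge volume =
capacity × a utilisation factor in [0.7, 0.95]; 5 replicates per (plant,
analyte), approximating the ~112-sample campaign over 21 plants. Per-cell
concentration means follow slope·population + intercept + group offset +
Normal(0, σ); class-level targets are ≈570 ng/L (parents) and ≈480 ng/L
(metabolites) at the mean population, split half slope / half intercept
and distributed over analytes with the skewed field composition (NIT and
DIN dominate parents; DN-IMI and DIN-U dominate metabolites). Group
offsets make agricultural/combined areas parent-rich and
industrial/combined areas metabolite-rich. Replicates are lognormal
(cv 0.2) because concentrations are positive and right-skewed; the
distribution is a modelling choice, not a measured fact. True removal
rates sit at 0.20–0.50 per compound (+0.05 for oxidation ditch, +0.20 for
UV) so plant means land in the 25–48% band conventional trains achieve.
A JSON sidecar records every generating parameter for recovery tests.

Not emulated: spatial land-use structure, rainfall/runoff dynamics,
correlated analyte panels, in-sewer kinetics, seasonal variation. Passing
tests therefore demonstrate correctness of the estimators under the stated
generating model — linearity in population, independent noise — not
robustness to real-data pathologies such as heteroscedastic or spatially
correlated residuals.

## Numerical choices

- Stage CSVs that later stages re-read are written with `%.17g` and parsed
  with round-trip float precision, so single-stage re-runs are bit-exact.
- Welch (unequal-variance) t-tests throughout; group pairs with fewer than
  2 plants are skipped with a warning; identical constant samples are
  reported as t = 0, p = 1 directly.
- Zero-variance correlation inputs return NaN rather than raising.
- p/m ratios: denominators are summed metabolite means (mass-consistent for
  multi-metabolite sets); zero denominators are excluded and logged, not
  mapped to infinity; the >100 exclusion applies before every aggregate,
  including group contrasts.
- Prediction lower bounds and predicted means are floored at 0; removal
  fractions are clipped to [0, 1] after every aggregation.
- Significance is read at p < 0.05 everywhere; `alpha_sig` defaults
  to 0.05.

## Problem sizes

Defaults: 21 sampled / 60 regional plants, 5 replicates, 4 literature
entries per cell (spread 0.10), 100,000 MC iterations. Simulation-based
tests use 200–1000 replicates per check (power checks 200, interval
coverage 1000, slope-CI coverage 500), sizes at which the binomial error
of the checked proportion is well inside the asserted bands.

## Known limitations

- Removal rates are process-class-level; plant-specific performance
  (loading, temperature, solids retention time) is not modelled.
- The class-level regression assumes one covariate; no multivariate or
  regularized variants.
- Uncertainty sources are independent by construction; correlated errors
  (e.g., flow and population) are out of scope.
- PNECs and per-analyte LOD/LOQ in the bundled panel are synthetic
  stand-ins anchored to published endpoint values; real assessments must
  supply their own tables.
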