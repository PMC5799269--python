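# Methods

## Model

A plant's root electrical capacitance C_R (nF, parallel capacitance at
1 kHz) rises roughly exponentially with the relative water saturation of
the soil around the roots, θ_rel ∈ [0, 1]. Normalising each plant's
readings by its own reading in water-saturated soil gives the relative
capacitance C_rel = C_R / C_R(θ_rel = 1), which collapses plants of very
different size onto one species curve

    C_rel = a · e^(b·θ_rel),

with C_rel(1) = 1 by construction (so a·e^b ≈ 1 up to fit residual).
Inverting gives the apparent saturation capacitance

    C_R* = C_R · k · e^(−b·θ_rel),   k = 1/a,

the soil-water-independent root-activity indicator used for all field
comparisons. The model's key empirical property, and the basis for using
one curve per species, is that (a, b) are independent of plant age and
size; species identity, by contrast, changes both.

All fitting is ln-scale ordinary least squares — the exponential model is
exactly linear in ln C_rel, and every R² quoted for these calibrations is
an ln-scale R². No nonlinear least squares is used anywhere.

### Pooling across plants

`fit_species` defaults to two-stage aggregation: per-plant OLS, then an
inverse-variance (precision-weighted) mean of the per-plant slopes and
intercepts. Because the normalisation already removes plant size, the
between-plant intercept variance is small by construction and this
two-stage estimator is essentially equivalent to a random-intercept mixed
model while being exactly testable against closed forms; the full mixed
model (statsmodels MixedLM, random plant intercept) is available via
`method="mixed"`. Noise-free inputs (zero per-plant standard errors) fall
back to an unweighted mean.

One consequence of self-normalisation worth knowing: the saturated point
is pinned at (1, 1), so a noise-free fit recovers the generating slope b
exactly but the intercept as e^(−b). For the shipped species constants
the difference |e^(−b) − a| is below 0.005 and immaterial in practice,
but exactness tests must use a saturation-consistent generator
(a = e^(−b)).

### Age and species effect tests

`test_age_species_effects` fits linear mixed models of ln C_rel on
θ_rel × age × species with a random plant intercept (ML), adding one term
at a time in the canonical order (main effects, two-way, three-way), and
reports sequential likelihood-ratio χ² statistics per term. Sequential
(hierarchical) tests are used rather than drop-one-term tests because
removing a main effect from a model that keeps its interactions is
re-absorbed by full-rank interaction coding and tests nothing. Age is
centred and scaled for numerical conditioning; optimizers are tried in
sequence (BFGS, L-BFGS, CG) when a Hessian is singular. Constant age
within a species drops the age terms with a warning.

### Two constant presets

Published rounded constants ("printed": maize k = 7.692, b = 2.028;
soybean k = 4.107, b = 1.392) reproduce published worked values
bit-faithfully; "derived" recomputes k = 1/a at full precision
(soybean 4.098 — the published 4.107 was rounded independently of a).
The choice is explicit everywhere and logged by the CLI; reproduction
tests use "printed".

## Field statistics

- **Day summaries**: arithmetic mean, sample SD (n−1), CV% of C_R* and
  θ_rel per measurement day and treatment.
- **Poolability**: one-way ANOVA across replicate row-segments/plots;
  pooling recommended iff p ≥ 0.05.
- **Two-sample comparisons** (consecutive days; control vs inoculated): a
  two-sided variance-ratio F pre-test at α = 0.05 selects Student vs
  Welch t. Stars use strict cutoffs (***, **, * at p < 0.001/0.01/0.05;
  p = 0.05 itself is NS).
- **Multi-group comparisons** (harvest shoot dry mass, AMF colonization):
  Bartlett's test gates one-way ANOVA + Tukey–Kramer (unequal n
  supported) vs Kruskal–Wallis + Dunn. Dunn's rank-based z tests are
  implemented in-package with tie correction and Bonferroni adjustment —
  the most common convention where the source procedure names none.
- **Day regressions**: within-day OLS of ln C_R on θ_rel across plants
  (n ≥ 5, non-degenerate θ spread required).

No multiplicity correction is applied across the consecutive-day test
sequence (raw per-pair stars are reported); this is a documented
limitation, matching field practice for descriptive time courses.

Applying the inversion to day *means* rather than per-reading values
incurs a Jensen gap (the transform is convex in θ_rel). At field-realistic
day dispersion (θ_rel CV ≲ 12.5%, C_R CV ≲ 26%) the relative gap is under
2% (`jensen_gap` computes it), which is why published day-mean worked
values are reproducible from day-mean inputs. Per-reading transformation
remains the primary path; day C_R* is the mean of per-reading transforms.

## Synthetic data

The generators emulate the study conditions, not generic data:

- **Pot** (`simulate_pot`): 15 plants/species, 10 θ_rel levels from near
  wilting point (0.204 = 0.097/0.476) to 1.0; root dry mass uniform on
  the observed harvest ranges (maize 0.37–11.10 g, soybean 0.32–6.21 g);
  saturated capacitance linear in RDM (3.8 and 2.05 nF/g, set so the
  largest plants reach the observed 42.1 / 12.7 nF maxima; relative noise
  0.20, giving mass-calibration R² near 0.85); multiplicative lognormal
  measurement noise with σ_ln = 0.10 on every reading, *including* the
  saturated one, which then defines the plant's own normaliser exactly as
  in the real protocol. The noise model is the package's choice (the
  source never states one); multiplicative lognormal is the natural
  companion of ln-scale fitting. At σ_ln = 0.10 on the default grid, the
  expected per-plant ln-scale R² is ≈ 0.96 — at the top of the observed
  per-plant range (0.854–0.959), so tests assert the one-sided property
  (fits at least as strong as the weakest observed) rather than a
  two-sided band.
- **Field** (`simulate_field`): a lookup-table seasonal template — one
  (DAS, mean θ_rel, θ CV, mean C_R*, BBCH) row per measurement day,
  derived from the published campaign tables via the printed constants —
  rather than a parametric curve, because the observed seasonal shapes
  are empirical. Per plant: θ_rel truncated-normal (rejection sampling
  into (0, 1]); true C_R* lognormal around the day mean (σ_plant = 0.10,
  sized to the observed day-level C_R* CVs of ~10–13%); measured C_R from
  the generating calibration with σ_ln noise. Soybean campaigns carry CON
  and INO treatments (n = 48 each across 3 groups); INO gets a +4.9%
  C_R* uplift inside DAS 40–90 (the size of the published 4-node-stage
  effect). θ_rel and C_R* are sampled independently within a day; any
  real covariance between plant size and local soil drying is not
  emulated — a caveat on what passing tests show about real data.
- **Soil** (`simulate_soil`): 300 pairs, θ_rel uniform on (0.2, 1],
  C_S = 350.3·θ^1.086 with lognormal σ = 0.13, derived analytically so
  the ln-scale fit R² lands near the observed 0.934.
- **Harvest** (`simulate_harvest`): soybean shoot dry mass grows along a
  logistic curve (rate 0.06/day, midpoint DAS 95) to a final control mean
  of 49.8 g with CV 0.30 (mean-preserving lognormal); sampling follows
  the trial design (6 plants/plot at DAS 48/71/99/135, 10/plot at the
  DAS-164 final harvest, 3 plots/treatment). The biomass uplift for INO
  (+25% inside the early window) is deliberately larger than the
  capacitance uplift: a ~5% biomass effect at n = 18 and CV 0.30 would be
  undetectable, whereas the emulated trial found clear early-season
  biomass differences. AMF colonization intensity rises logistically from
  ~20% before pod filling to ~80% at ripening (SD 7 points, clipped to
  [0, 100]); grain mass (≈ 0.39 × SDM) only at the final harvest.

All generators are bit-deterministic under a fixed seed
(`numpy.random.default_rng`); a fixed config + seed reproduces every CSV
byte-for-byte.

## Numerical and edge-case choices

- θ_rel marginally above 1 at ingest (≤ 1.02, instrument noise around
  saturation) is clamped to 1 with a logged warning; larger values are
  validation errors. Saturation is a physical ceiling.
- Volumetric SWC → θ_rel conversion happens only at ingest, using the
  soil's saturation constant (default 0.476 cm³ cm⁻³).
- Fits require ≥ 3 distinct abscissa values; zero variance anywhere is a
  `FitError`, not a NaN.
- Identical-sample comparisons short-circuit to p = 1 / NS rather than
  relying on a 0/0 t statistic.
- Constants are rounded (3 decimals) only at presentation; full precision
  is kept internally, and k·a = 1 holds to machine precision for derived
  calibrations.
- Acceptance-style recovery runs use 20 replicates of the default designs
  (15 plants × 10 levels; n = 300 soil pairs) — enough for the replicate
  mean of the slope to stabilise well inside ±0.05.

## Known limitations

- The calibration constants are specific to one soil; soil-type effects
  on the C_rel–θ_rel curve are out of scope.
- C_R* is a relative indicator: conversion to absolute root surface area
  or water-uptake volume is not attempted.
- The soil-dominance sanity check (C_S ≫ C_R) holds with an order of
  magnitude to spare for typical plants, but the very largest maize
  plants approach saturated soil capacitance within a factor of ~8
  (346 nF vs a 42 nF plant), so the strict ≥10× reading fails at the
  extreme; checks assert ≥10× for soybean everywhere and for the maize
  median.
- Field plants are re-sampled each day; no repeated-measures structure is
  modelled, matching the emulated design.
- BBCH phenology codes are pass-through labels; no staging logic.
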