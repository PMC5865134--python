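# Methods

## Model

For region i with observed count `O_i` and expected count `E_i` (from
indirect age–gender standardisation):

    O_i ~ Poisson(μ_i)
    log μ_i = log(E_i) + α + x_i'β + u_i + v_i

- `u` — intrinsic conditional-autoregressive (ICAR) field over the
  Queen-contiguity graph: conditional on the rest, `u_i` is normal with
  mean the average of its neighbours and precision `τ_u · n_i` (n_i =
  number of neighbours). The joint density is improper (precision
  `τ_u (D − W)` has one null vector per connected component), resolved by
  constraining `u` to sum to zero within every component.
- `v_i ~ N(0, 1/τ_v)` — exchangeable extra-Poisson noise.
- `x_i` — reference-cell dummy coding of categorised covariates; category
  1 of each covariate is the reference, so `exp(β)` is the SIR ratio of a
  category against the covariate's first category.
- Smoothed SIR of region i: `μ_i / E_i`, summarised by the posterior
  median with an equal-tailed 95% credible interval; a region is
  "elevated" when the interval's lower bound strictly exceeds 1.

Priors: `τ_u, τ_v ~ Gamma(0.5, 0.0005)` (shape, rate — the conventional
"uninformative" precision prior of the classic disease-mapping software
stack), `α, β_j ~ N(0, 10^6)`. All are configurable through
`BYMModelSpec`. The intercept absorbs the overall level, so the ICAR
constraint identifies `u`.

## Sampler

Metropolis-within-Gibbs, one long loop per chain (numba-compiled):

1. each `u_i`: random-walk Metropolis against ICAR conditional × Poisson
   likelihood of region i (islands — degree-0 regions — have `u_i ≡ 0` and
   rely entirely on `v_i`);
2. re-centring: per-component means are subtracted from `u`; the removed
   overall mean is added to the intercept (for a connected graph this is an
   exact reparametrisation along the prior's null direction, leaving every
   `μ_i` unchanged);
3. each `v_i`, then `α`, then each `β_j`: random-walk Metropolis;
4. `τ_u | u ~ Gamma(a + rank/2, b + u'(D−W)u/2)` with rank = n − (number of
   components), and `τ_v | v ~ Gamma(a + n/2, b + Σv²/2)` — exact conjugate
   draws.

Step sizes adapt only during burn-in (×1.25 above 50% acceptance, ×0.8
below 20%, every 100 sweeps) and are frozen afterwards, so the retained
draws come from a fixed, detailed-balance-preserving kernel. Chains are
seeded independently through `numpy.random.SeedSequence`; runs are
reproducible bit-for-bit for a fixed configuration.

Chain lengths. `MCMCConfig()` defaults to the production protocol: 2
chains, 100,000 burn-in, 500,000 iterations, keep every other draw.
`MCMCConfig.desk()` (2 × 5,000 + 20,000, thin 2) is the scale used for the
package's own simulation studies; at ~80 regions one desk-scale fit takes
about a second, so replicated studies stay in the minutes. The
null-calibration study runs 100,000 iterations instead of 20,000: with no
true structure the two variance components are only weakly identified, and
their batch-means MC error needs the longer run to fall safely below 5% of
the posterior SD; this mirrors the production protocol's generous run
length. Thinning is applied after burn-in (the alternative — thinning the
burn-in too — only changes what is discarded).

## Diagnostics

- **Gelman–Rubin**: classic `R̂ = sqrt(((n−1)/n · W + B/n)/W)` over ≥2
  chains, with the Brooks–Gelman–Rubin trajectory computed on growing
  prefixes for visual inspection.
- **Monte Carlo error**: batch means, 50 batches, `SE = SD(batch means)/√50`;
  reported as a ratio to the posterior SD (the usual "below 5%" working
  rule).
- **DIC**: `D(μ) = −2 Σ_i [O_i log μ_i − μ_i − log O_i!]`; `D̄` averages the
  deviance over draws, `D̂` evaluates it at the posterior mean of `μ`,
  `pD = D̄ − D̂`, `DIC = D̄ + pD`. Smaller is better; `pD` is the effective
  parameter count.

## Standardisation

Standard rates divide state-wide stratum caseloads by stratum populations
(18 strata: {male, female} × {0–9, …, 80+}); expected counts apply those
rates to each region's stratified population. A single fixed population
table serves as the denominator (no interpolation across study years).
When the regions partition the standard population, `Σ_i E_i` equals the
state caseload exactly — this identity is asserted to 1e-9 relative error
in the tests. Regions with `E = 0` and `O = 0` have an undefined SIR; they
are flagged and excluded from modelling with a warning (with `O > 0` the
standardisation is inconsistent and the code raises). Case rates are
`10,000 · O_i / ERP_i`.

## Covariate handling

Continuous covariates are cut at their 20/40/60/80 percentiles
(linear-interpolation percentile rule, computed unweighted over regions);
a value equal to a boundary joins the upper category, matching the
"≥ cut-point" convention of published category tables. Externally
categorised covariates (e.g. a six-class remoteness index) bypass the
quintile computation via `precategorised`. Correlated covariate families
(e.g. the four SEIFA socioeconomic indices) are represented in
multivariable modelling by a single configured member
(`select_seifa_representative`).

Selection: univariable BYM fits rank covariates by DIC; the multivariable
model adds them in that order and retains a covariate when at least one of
its category coefficients has a 95% CrI excluding zero (equivalently, a
SIR-ratio interval excluding 1 — the exp transform is monotone, so the two
rules agree exactly). Categorical covariates enter and leave as whole
blocks, and selection is forward-only: a covariate added earlier is not
removed if a later addition erodes its significance. A screen failure for
one covariate is recorded on its result rather than aborting the others.

## Synthetic data

The generator emulates an area-level ambulance-study dataset:

- **Lattice**: 8×10 grid of unit squares (~80 regions, the scale of a
  state's local-government areas). Queen contiguity on the grid gives
  degrees 3 (corners) to 8 (interior); real administrative maps have lower
  median degree (~5), which affects nothing structural in the tests.
- **Population**: per-region totals uniform in 20,000–60,000, split into
  the 18 strata by a multinomial draw around a fixed adult-skewed pyramid.
- **Baseline rates**: per-stratum case rates rising steeply with age
  (0.001 → 0.020 per person per study window) with a male excess placing
  ~55% of cases in males; overall ~0.0065 cases per person, so a typical
  region expects a few hundred cases — the caseload scale of a multi-year
  state-wide study.
- **Spatial effects**: `u` is drawn *exactly* from the intrinsic CAR
  distribution via the eigendecomposition pseudo-inverse of `τ_u (D − W)`
  with per-component centring (chosen over approximate Gibbs warm-up so
  that density oracles are exact); `v` is iid normal. Default
  `τ_u = τ_v = 10` (random-effect SDs ≈ 0.32, i.e. region risks mostly
  within ±2× of baseline) — the paper-scale analysis reports no variance
  components, so this is a design choice of plausible magnitude, not a
  calibration.
- **Counts**: Poisson at stratum level with region-level relative risk
  `exp(x'β + u + v)`, aggregated both to region totals and to state-wide
  stratum totals so downstream standardisation re-derives the standard
  rates from the data itself.
- **Covariates**: optional simultaneous-autoregressive smoothing
  `x = (I − ρ W_row)^{-1} z` produces positive neighbour correlation.

What the generator does **not** emulate: repeat callers, within-region
heterogeneity of the age pyramid, irregular polygon geometry, missing-data
windows, or population change over time. Passing tests therefore
demonstrate the correctness and calibration of the machinery under the
generative model, not robustness to those real-data features.

## Validation studies and what they show

- **Conservation** — exact (to float) identity of indirect standardisation.
- **Oracle equivalence** — expected counts vs a brute-force double loop;
  Poisson log-likelihood vs exact factorials; the ICAR quadratic form vs a
  dense-Laplacian product; Queen adjacency vs an exact closed-interval
  overlap oracle on random rectangle tilings (which contain T-junctions)
  and the analytic grid rule on lattices.
- **Parameter recovery** — 50 replicates with a known two-category effect
  β = 0.7: 95% CrI coverage ≈ 96%, posterior-median risk-ratio bias ≈ 1%.
- **Null calibration** — with all effects zero, ≈100% of smoothed-SIR CrIs
  contain 1; R̂ < 1.01 and MC error < 3% of SD for all monitored
  parameters.
- **Stepwise operating characteristics** — the truly predictive covariate
  is retained in ~100% of replicates. Exclusion of a five-category null
  covariate requires all four of its coefficient CrIs to contain zero, so
  even at nominal per-category error the familywise exclusion rate is
  about 0.95⁴ ≈ 0.81; measured over 80 replicates it is 76% (per-category
  false-positive rate 7.5%, slightly above nominal — posterior intervals
  for small-group contrasts under the hierarchical null are not exactly
  frequentist-calibrated). This is a known limitation of block-wise
  significance retention rather than of the implementation, and it is
  insensitive to chain length.

## Numerical choices and edge cases

- Quantile and percentile computations use linear interpolation throughout
  (quintile boundaries, credible intervals, median/IQR of ages).
- Ties at a category boundary go to the upper category.
- Elevated-risk flags use a strict inequality (lower bound exactly 1 is not
  elevated).
- Polygon coordinates are snapped to a 1e-9 grid before contiguity testing.
- GAL files use the GeoDa dialect (count header; id/degree line followed by
  a neighbour-id line); asymmetric files are rejected naming the offending
  pair.
- Degenerate posteriors (zero spread) yield zero-width CrIs and `pD = 0`
  rather than errors; non-finite sampler output aborts with a state
  summary.
- Exports print full-precision decimals; re-reading with a round-trip
  float parser reproduces values bit-for-bit.
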