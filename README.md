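# carmap

Bayesian disease mapping for area-level emergency incidence: indirect
age–gender standardisation, smoothed standardised incidence ratios (SIRs)
via a Besag–York–Mollié (BYM) conditional-autoregressive Poisson model, and
quintile-covariate spatial regression with DIC-ordered stepwise selection.

## The problem

Counts of medical emergencies attended in small administrative areas (such
as the ~80 Local Government Areas of an Australian state) are too noisy to
compare directly: sparsely populated areas produce wildly unstable rates,
and neighbouring areas are correlated. The standard small-area approach is:

1. **Indirect standardisation.** Stratify the state caseload and population
   into 18 age–gender groups (males and females in 10-year bands 0–9 …
   80+), form standard rates `sr_g = cases_g / population_g`, and give each
   area an expected caseload `E_i = Σ_g pop_{i,g} · sr_g`. The crude SIR is
   `O_i / E_i`.
2. **Spatial smoothing.** Model the counts as

   ```
   O_i ~ Poisson(μ_i),   log μ_i = log(E_i) + α + x_i'β + u_i + v_i
   ```

   where `u` is a spatially structured effect with an intrinsic CAR prior
   over the Queen-contiguity graph (each `u_i | u_-i` is normal around the
   mean of its neighbours with precision `τ_u · n_i`, sum-to-zero per
   connected component) and `v_i ~ N(0, 1/τ_v)` is unstructured noise. The
   smoothed SIR of area i is `μ_i / E_i`; an area is flagged *elevated*
   when the lower bound of its 95% credible interval exceeds 1.
3. **Ecological regression.** Area covariates (socioeconomic indices,
   remoteness, vehicle access, …) are cut into quintiles; each enters the
   model as reference-cell dummies. Covariates are screened one at a time,
   then added to a multivariable model in ascending order of univariable
   DIC and retained when at least one category coefficient has a 95% CrI
   excluding zero.

The model is fitted by a Metropolis-within-Gibbs sampler written in this
package (numba-compiled inner loop): conjugate Gamma updates for the
precisions, per-site random-walk Metropolis for `u`, `v`, intercept and
coefficients, with sum-to-zero re-centring each sweep. Convergence is
monitored with the Gelman–Rubin statistic (and its Brooks–Gelman–Rubin
trajectory) and batch-means Monte Carlo error; model fit with the deviance
information criterion.

Because real ambulance/census extracts of this kind are not public, the
package ships a first-class synthetic-data generator (`carmap.synthetic`)
producing lattices of regions, stratified populations, spatially correlated
covariates, exact intrinsic-CAR fields and Poisson counts with known ground
truth, so the entire pipeline is testable end to end.

## Worked example

The `analysis/` drivers run the whole study on a synthetic 80-region area
(one covariate, `x1`, truly carries a dose-response up to log-risk 0.7 in
its top quintile; `x2`, `x3` are noise):

```
$ python analysis/01_simulate.py
simulated 80 regions, 35272 cases (population 3,264,376); x1 carries a dose-response up to log-risk 0.7, x2/x3 are noise

$ python analysis/02_standardise.py
standardised 80 regions: total observed 35272, total expected 35272.00 (conservation error 0.00e+00)
case rates span 28.38-395.83 per 10,000; crude SIR 0.26-3.64

$ python analysis/03_fit_sir.py
27 of 80 regions flagged elevated (95% CrI lower bound > 1); smoothed SIR spans 0.28-3.62
convergence: max R-hat 1.0110, max MC error 10.2% of SD; DIC 779.5 (pD 78.8)
smoothing pulled 88% of regions towards SIR 1

$ python analysis/04_covariate_models.py
univariable screen (ascending DIC):
  x1: DIC 778.6, 3 significant categories
  x3: DIC 779.4, 0 significant categories
  x2: DIC 779.8, 0 significant categories
stepwise retained: ['x1']; final DIC 779.1
  x1 top quintile: SIR ratio 2.50 [1.75, 3.44]

$ python analysis/05_report.py
35272 cases: 69.7% hypoglycaemia, 30.3% hyperglycaemia; 55.7% male; median [IQR] age 55 [36, 70]
top quintile of x1: 150% increased risk (SIR 2.50, 95% CrI [1.75, 3.44])
```

Reading the output: expected caseloads conserve the state total exactly (the
algebraic identity of indirect standardisation); the smoother shrinks
unstable crude SIRs towards 1 while preserving genuinely elevated areas;
the stepwise keeps the truly predictive covariate (its top-quintile risk
ratio of 2.50 [1.75, 3.44] covers the true e^0.7 ≈ 2.01) and drops both
noise covariates; and the SIR→percent translation reads a ratio of 2.50 as
150% increased risk.

The same pipeline is scriptable from the shell (`carmap simulate`,
`carmap standardise`, `carmap fit`, `carmap regress`, `carmap report`) over
CSV/GAL/GeoJSON files.

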