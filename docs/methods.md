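# Methods

## The model

The response is grassland net primary productivity (NPP, gC·m⁻²·yr⁻¹)
aggregated to small watersheds, modelled on the natural-log scale. With
observation occasions t (level 1) nested in watersheds i (level 2)
nested in counties j (level 3), the unconditional growth model is

    log(NPP_tij) = π000 + π100·T_tij + β2·T²_tij
                   + μ_0ij [+ μ_1ij·T] + e_00j [+ e_10j·T] + ε_tij

with independent Gaussian random effects per level and i.i.d. residuals:
Var(μ_0ij) = τ_w00, Var(e_00j) = τ_c00, Var(ε) = σ². Time is coded
T = calendar year − 1988, so the intercept is expected log-NPP at the
first observation year and T² is built from the same origin (a centred-T
variant is available through `ModelSpec.time_origin` if collinearity is
a concern). Random time slopes with unstructured 2×2 covariance are
supported at both levels; the intercept-only structure is the default for
the ladder because the variance decomposition below is defined on
intercept components.

The conditional ladder adds fixed effects cumulatively:

| step | added terms |
|---|---|
| 2 | climate mains + quadratics (precipitation, temperature, sunlight) |
| 3 | grassland_pct, grassland-type dummies (ref. ASAG), NNR dummy, and T× each |
| 4 | watershed traits: dem, slope, soil N/P/K, distances to water/highway/village |
| 5 | county socioeconomic mains: GDP, HPD, meat production |
| 6 | T×climate and grassland_pct×socioeconomic interactions |

The exact membership of intermediate steps is a modelling choice, not a
law; the ladder is therefore overridable per step. Covariates are
z-scored (`standardize`) against a declared SD table before fitting, so
coefficients are per-SD proportional changes in NPP; the NNR factor is
used as a binary in/out dummy by default, with the four-level zone
factor retained in the data.

Variance decomposition uses intercept components only, also when random
slopes are fitted:

    ICC_w = τ_w00 / (σ² + τ_w00 + τ_c00),   ICC_c = τ_c00 / (σ² + τ_w00 + τ_c00)

so the triple (ICC_w, ICC_c, residual share) always sums to one.
`variance_shares` reports the proportional reduction of each component
between two fits on the same rows, the standard "variance explained"
comparison along the ladder.

## Estimation

The mixed-model core is written from scratch. The marginal covariance is
block diagonal by county; each block is

    V_j = σ² [ I + Z_w (τ_w/σ²) Z_w' + Z_c (τ_c/σ²) Z_c' ]

and all linear algebra is dense per-block Cholesky (block sizes are a
few hundred rows at study scale). σ² and the fixed effects are profiled
out in closed form, leaving an optimisation only over the relative
covariances τ_l/σ², parameterised by log-Cholesky factors — positive
semi-definiteness is automatic and the τ→0 boundary is approached
smoothly as a diagonal log-entry → −∞.

* Criterion: ML by default (an AIC is reported, and the AIC convention
  counts fixed effects plus all free variance parameters including σ²);
  REML by flag. Fixed effects are GLS at the optimum; their covariance is
  σ̂²(X'V*⁻¹X)⁻¹ and reported t statistics are asymptotic z (no
  Satterthwaite/Kenward–Roger small-sample correction).
* Optimiser: Nelder-Mead on the profiled deviance from moment-based
  (nested-ANOVA) starting values, followed by a BFGS polish; tolerances
  1e-10 on the deviance and 1e-7 on the gradient norm. Everything is
  deterministic — fixed starting point, no randomness — so a fit is a
  pure function of the data.
* BLUPs are Γ Z' V*⁻¹ r per group at the optimum; `predict_trajectory`
  returns population-level (fixed-effects-only) curves or BLUP-shifted
  group curves, flagged as such.
* Likelihood-ratio tests require ML (REML fits with different fixed
  parts are refused) and the output carries a caveat that a
  variance-on-the-boundary null makes the χ² reference conservative.
  The "mixed model vs pooled OLS" comparison in the pipeline report
  implements the baseline as ordinary least squares with all grouping
  ignored.
* Degenerate designs: identically-zero design columns are excluded from
  the solve and reported with coefficient 0 and NaN standard error
  (they carry no information and would otherwise trigger a spurious
  singularity); genuinely collinear non-zero columns raise an error that
  names them.

Checks in the test suite: exactness of the marginal log-density against
dense multivariate-normal evaluation; closed-form ANOVA estimators on
balanced one-way layouts (REML: MSW and (MSB−MSW)/m; ML: MSW and
(SSB/k−MSW)/m); and agreement with an independent established
mixed-model implementation to 1e-4 relative on 200-row nested instances.

## The trend and accounting stages

The per-pixel slope uses the rank-index closed form (i = 1..n), which is
algebraically the OLS slope; the six observation years are unevenly
spaced, and using rank versus calendar spacing is a deliberate choice
exposed through `time_index`. Significance is the regression F test with
(1, n−2) df; the five-way grading uses half-open intervals so P = 0.05
is "no change" and P = 0.01 is "significant", not "extremely". A series
of only two points has a defined slope but an undefined p-value, and is
flagged rather than graded. Whether one should test six raw points or an
annual interpolation is a judgement call; the package tests the points
it is given.

The conversion accounting credits converted-in pixels with their full
end-date NPP and debits converted-out pixels with their full start-date
NPP — the minimal additive scheme in which the three components
reproduce total grassland NPP change exactly. Shares are reported
relative to |Δtotal| and can individually exceed 100% in magnitude when
in/out flows nearly cancel. Totals are Σ(value·area) with the mass unit
carried through opaquely; the area-weighted mean always equals
total/area by construction.

## The synthetic generator

`generate_panel` emulates the study conditions: 18 counties, ~100
watersheds per county (an explicit per-county list reproduces the exact
1,817 of the real hierarchy), six years 1988–2012, responses built on
the log scale from the fixed linear predictor evaluated on z-scored
covariates plus county and watershed draws plus N(0, σ²) residuals, then
exponentiated. Missingness is independent Bernoulli at 2.2% (the rate
implied by 10,663 usable rows out of 10,902 possible; the true mechanism
is unknown, so MCAR is the honest default).

Defaults are the study conditions: variance components σ² = 0.160,
τ_w00 = 1.781, τ_c00 = 1.354; quadratic fixed trend (5.135, −0.000,
0.001); covariate SDs from the reference descriptive statistics (precipitation
158.5 mm, temperature 2.28 °C, sunlight 201.05 h, grassland 23.99%, DEM
395.18 m, slope 5.8°, soil K/N/P 37.17/0.17/0.01%, distances
28.12/196.65/55.76 km, GDP 149 million CNY, HPD 30.6 thousand
people·km⁻² taken at face value as a scaling constant, meat 2.66
thousand tons). Covariate means are free knobs (the models consume
z-scores, so means are immaterial to recovery) set to plausible
alpine-plateau values. Where the literature gives a standardized
coefficient it is used as the generative default (grassland 0.033, GDP
−0.093, HPD −0.299, meat 0.146, T×grassland −0.003, grassland×GDP
−0.021, grassland×HPD −0.009, grassland×meat 0.006); remaining
coefficients realise the documented sign pattern (hump-shaped climate
response, negative T×precipitation, positive T×temperature, negative
topography, positive soil fertility) at magnitudes of the same order.
Random intercept+slope is the generator default (slope variances 0.002
and 0.001, i.e. slope SDs of a few percent per year — large enough to
matter over 24 years, small against the intercept spread); intercept-only
is a flag. Grassland types are drawn with meadow rare (~1%) and
ASAG/ASAM dominant; reserve zones cover slightly over half of
watersheds.

What the generator does **not** emulate: spatial autocorrelation of
residuals or covariates, the real joint covariate distribution
(covariates are independent Gaussians), non-random missingness, and
measurement error in the NPP retrieval itself. Passing recovery tests
therefore demonstrates the correctness of the estimators under the
stated model, not robustness to those violations.

`generate_grid` is a deliberately simple fixture for the raster stages:
per-pixel series intercept + slope·t + noise, land-use layers realising
requested retained/in/out transition fractions up to integer rounding.

## Problem sizes and statistical design of the checks

The recovery checks fit the full study scale once (18×100 watersheds,
~10.6k rows) and run replicate-based checks (CI coverage, median
component error, interaction-sign recovery) at 18×25 or 12×15 scale with
100 replicates each — sizes chosen so the Monte-Carlo error of the
summary is a few percent and the whole suite stays in the minutes range.
One statistical subtlety: with only 18 counties the *realized* variance
of the county draws has ~33% sampling error, far larger than the
estimator's error, so county-component recovery is judged against the
realized variance of the returned draws (the generator hands those back
for exactly this purpose); the residual and watershed components, with
thousands of effective replicates behind them, are judged against their
nominal values. Wald 95% intervals with z quantiles undercover slightly
at 18 counties (a t with ~17 df would be wider), which is why the
coverage band is [0.92, 0.98] rather than a point at 0.95.

## Known limitations

* No crossed random effects, non-Gaussian responses, or spatial/temporal
  residual correlation structures.
* Grid I/O is plain `.npy` + JSON sidecar; no geospatial metadata
  (projection, transform) is carried, so georeferenced rasters must be
  converted upstream.
* The LR test for variance components does not implement boundary-aware
  mixture reference distributions; it flags the issue instead.
* Annual growth rates are convention-dependent (arithmetic vs geometric
  over an ambiguous year count); both are exposed and neither is
  privileged.
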