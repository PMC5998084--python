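# grassnpp

Tools for analysing change in grassland **net primary productivity (NPP)**
across a nested landscape of small watersheds within counties — the
setting typical of alpine-plateau grassland monitoring, where ~1,800
watersheds inside 18 counties are observed at a handful of unevenly
spaced years (1988, 1995, 2000, 2005, 2008, 2012).

The package is aimed at ecologists and environmental statisticians who
want to separate *where* productivity variation lives (time vs watershed
vs county) and *what drives it* (climate, grassland cover and type, soil,
topography, socioeconomic pressure), with every stage testable end to end
on synthetic data with known ground truth.

## What it computes

**Per-pixel trend grading.** For each pixel's NPP series the trend slope

```
theta_slope = (n Σ i·NPP_i − Σ i · Σ NPP_i) / (n Σ i² − (Σ i)²),   i = 1..n
```

is tested with the regression F statistic (1, n−2 df) and graded into
five classes: extremely significant decrease (slope < 0, P < 0.01),
significant decrease (slope < 0, 0.01 ≤ P < 0.05), no significant change
(P ≥ 0.05), significant increase, extremely significant increase.

**Change accounting under land-use conversion.** Total grassland NPP
change between two dates decomposes exactly over transition classes:
retained grassland (G-G) contributes Σ(end − start), conversion into
grassland (O-G) contributes Σ end, conversion out (G-O) contributes
−Σ start, and the three sum to the total change.

**Three-level growth models.** With time t nested in watershed i nested
in county j, the core model is

```
log(NPP_tij) = π000 + π100·T + β2·T² + (covariate terms)
               + u_0ij + e_00j + ε_tij
u_0ij ~ N(0, τ_w),  e_00j ~ N(0, τ_c),  ε_tij ~ N(0, σ²)
```

estimated by a from-scratch profiled ML/REML optimiser (log-Cholesky
parameterisation, GLS fixed effects, BLUPs, AIC, LR tests; random
time slopes at either level optional). Variance is decomposed through
intraclass correlations,

```
ICC_watershed = τ_w / (σ² + τ_w + τ_c),   ICC_county = τ_c / (σ² + τ_w + τ_c),
```

and a stepwise conditional ladder (climate → grassland → watershed
traits → socioeconomic → cross-level interactions) tracks how much
between- and within-group variance the predictors absorb. Covariates
enter as z-scores, so coefficients read as proportional NPP change per
one SD of the covariate.

## Worked example

```python
import grassnpp as g

cfg = g.SyntheticConfig(
    n_counties=18, watersheds_per_county=25, random_slopes=False,
    fixed_effects={"intercept": 5.135, "T": -0.000, "T2": 0.001},
    sigma2_resid=0.160, tau_watershed=[[1.781]], tau_county=[[1.354]],
    missing_rate=0.022, seed=1)
panel, truth = g.generate_panel(cfg)
fit = g.unconditional_growth(g.standardize(panel))
dec = g.icc(fit)
```

prints, via the obvious format strings,

```
panel: 2631 rows, 450 watersheds, 18 counties
sigma2=0.155  tau_w=1.751  tau_c=1.231
ICC_watershed=0.558  ICC_county=0.392
intercept:  5.2639 (se 0.2694)
        T: -0.0023 (se 0.0033)
       T2:  0.0010 (se 0.0001)
```

i.e. the quadratic growth model recovers the generative components
(0.160 / 1.781 / 1.354) and fixed effects (5.135 / −0.000 / 0.001)
within sampling error, and most log-NPP variance sits between
watersheds, then between counties, with little left within series.

The raster side:

```python
grid = g.generate_grid((50, 50), {"slope": 2.0, "noise_sd": 2.0},
                       {"retained": 0.85, "in": 0.05, "out": 0.05}, seed=2)
tm = g.trend_map(grid.npp_stack, mask=grid.landuse_start == "grassland")
chg = g.decompose_change(grid.npp_stack[0], grid.npp_stack[-1],
                         grid.landuse_start, grid.landuse_end)
```

gives

```
{'ext_sig_decrease': 0.0, 'sig_decrease': 0.0, 'no_change': 11.96,
 'sig_increase': 38.8, 'ext_sig_increase': 49.24}
delta_total=22908.0  retained=21625.3  in=32766.4  out=-31483.7
```

a grid with a true upward trend of 2 units per step graded mostly as
(extremely) significant increase, and a conversion ledger whose three
components sum exactly to the total change.

A `grassnpp` console script exposes the same stages
(`simulate`, `trend`, `fit`, `icc`, `decompose`, `report`); the `report`
subcommand runs the whole pipeline from a YAML config and embeds the
config hash, seed and version in its JSON report, so a run is
reproducible bit for bit.

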