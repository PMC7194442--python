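# wetland-svc

Bayesian spatial Poisson regression with a **spatially varying wetland-cover
coefficient**, for analyses that ask how the association between landscape
wetland cover and species richness changes across a subcontinental study
area — plus the geospatial preprocessing that builds the model's inputs
(kernel-density cover surfaces, simple kriging of sparse climate points,
collinearity screening, and decadal cover-change rasters).

Intended users are spatial ecologists and biostatisticians who have
gridded richness counts and point/raster land-cover data and want
region-resolved, uncertainty-qualified effect maps rather than a single
continental slope.

## Model

Counts are conditionally independent Poisson on a regular grid of sites
*s* with centroid location *l*ₛ:

    yₛ | ηₛ ~ Poisson(exp(ηₛ)),      ηₛ = zₛ'α + xₛ β(lₛ) + ψ_region(s)

* **zₛ** — intercept plus fixed covariates (elevation, precipitation,
  temperature), z-scored; α ~ N(0, 1000·I).
* **xₛ** — wetland cover at the site; its effect **β(·)** is a
  two-dimensional piecewise-constant (degree-0) tensor-product spline on a
  knot grid: β(l) = φᵢⱼ for l in cell (i, j).  The coefficients carry an
  intrinsic CAR (ICAR) penalty, φ | σ⁻² ~ N(0, σ⁻²(D_φ − W_φ)), where W_φ
  is rook adjacency of the knot cells — a 2-D Bayesian P-spline that
  discourages abrupt changes in the effect surface.  Cells containing no
  sites are trimmed before fitting (Q kept coefficients).
* **ψ** — region-level random effects (one per contiguous region,
  emulating watershed units) with their own ICAR prior at precision τ⁻²;
  they absorb residual spatial dependence that the surface and covariates
  miss.
* Hyperpriors: σ⁻², τ⁻² ~ IG(1, 1).

Sampling is by adaptive Metropolis-within-Gibbs (block random walks with
Robbins–Monro scale tuning and Haario-style covariance shaping during
burn-in only), with equal-tailed 95% credible intervals; a surface cell is
called significant when its interval excludes zero.  Correctness is
established against deterministic quadrature on reduced models, structural
identities of the CAR/spline machinery, and parameter recovery on
synthetic data with known truth.

## Worked example

The `analysis/` scripts run the whole study on simulated data with known
ground truth (surface bands −0.5 / 0 / +0.5, α = (1.0, −0.5, 0.3, 0.0)):

```bash
python analysis/01_simulate.py      # site table, points, rasters
python analysis/02_preprocess.py    # filter, KDE, kriging, screen, change
python analysis/03_fit.py           # MCMC fit + no-random-effect check
python analysis/04_summarize.py     # surface, significance map, tables
```

Output from a run with the default seed:

```
model: 2500 sites, P=4 fixed effects, Q=36 spline cells, R=6 regions
no-random-effect residuals: Moran's I = 0.048 (null expectation -0.0004),
permutation p = 0.001 -> spatially dependent
fixed effects (posterior mean [95% CI]):
  intercept  +1.011 [+0.946, +1.078]*
  elev       -0.523 [-0.549, -0.494]*
  precip     +0.302 [+0.272, +0.335]*
  temp       +0.000 [-0.030, +0.032]
surface: 13 cells significantly positive, 12 negative, 11 not significant (of 36)
vs truth: sign agreement 100% in strong-signal cells; 95% CIs cover the
true cell value in 94% of cells
```

Reading this: the fixed effects recover their true values (the temperature
effect is truly zero and is correctly not significant); the misspecified
no-random-effect fit leaves significantly autocorrelated residuals, which
is exactly why the region effects are in the model; and the fitted
coefficient surface recovers the sign of the wetland effect everywhere the
true effect is strong, with calibrated interval coverage.

A thin CLI over the same library is also installed
(`wetland-svc simulate|preprocess|fit|summarize`).

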