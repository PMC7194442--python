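# Methods

## The model

The response is a per-cell species-richness count on a regular grid of
10×10 km sites.  Conditional on its linear predictor, each count is
Poisson:

    y_s | eta_s ~ Poisson(exp(eta_s))
    eta_s = z_s' alpha + x_s beta(l_s) + psi_{region(s)}

with z_s the intercept and fixed covariates, x_s the wetland cover at the
site, beta(.) the spatially varying wetland effect, and psi a region-level
random effect.  The model's premise is that wetland cover can help or hurt
richness depending on where you are, so beta is a surface, not a scalar.

**The coefficient surface.**  beta is expanded in a two-dimensional
piecewise-constant (degree-0) tensor-product B-spline basis: k1 and k2
regularly spaced interior knots partition the domain into m1×m2 cells
(m = k + 1 per direction), and beta(l) equals the coefficient phi_ij of
the cell containing l.  Exactly one basis function is active anywhere
(partition of unity).  Cell indexing is row-major with the north–south
index fastest, cells are half-open [a, b) with the final north/east edge
closed, and cells containing no sites are trimmed before fitting, leaving
Q coefficients.  Knot cells are deliberately numerous; overfitting is
controlled by the prior, not the knot count (the P-spline idea).

**Priors.**  phi carries an intrinsic CAR prior with precision
sigma^-2 (D_phi − W_phi), where W_phi is rook adjacency among *kept* cells
(two kept cells separated by a trimmed cell are not neighbors) and D_phi
the degree matrix.  The same construction at the region level gives
psi | tau^-2 ~ N(0, tau^-2 (D_psi − W_psi)), regions being adjacent when
some pair of rook-neighboring sites straddles them.  Fixed effects get
independent N(0, 1000) priors — including the intercept, since that is
the only prior variance the model states — and both precision scales get
IG(1, 1) hyperpriors.  The ICAR densities are improper: only the quadratic
form −(s/2) x'(D−W)x enters the posterior, plus a rank-adjusted
(rank/2)·log s term (rank = dimension − number of graph components) so
the scale updates are proper.

**Identifiability.**  An ICAR prior is invariant to constant shifts, so
two flat directions need care.  The region effects are *exactly*
confounded with the intercept; psi is therefore restricted to the
sum-to-zero subspace of each graph component (proposals are projected, and
the synthetic generator simulates on the same subspace).  The surface
level is different: shifting all phi by c changes eta by c·x_s, which
varies across sites, so the phi level is likelihood-identified and must
NOT be constrained away — pinning it would silently remove the model's
ability to represent a surface with nonzero mean.  The level is instead
only *weakly* identified (it trades off against the intercept through the
mean of x), which is a sampling problem, handled below, not a model
problem.

## Sampling

Adaptive Metropolis-within-Gibbs with Gaussian random-walk blocks:

* alpha as one block; phi in spatially contiguous sub-blocks (4×4
  super-cells of the knot grid by default); psi as one block with
  sum-to-zero projection; sigma^-2 and tau^-2 by random walks on the log
  scale (the IG prior on the *precision* is not conjugate to the Gaussian
  quadratic form — the full conditional is generalized inverse Gaussian —
  so there is no Gibbs draw); and one full joint block over
  (alpha, phi, psi).
* Two burn-in-only adaptations: Robbins–Monro tuning of each block's
  proposal magnitude toward 0.234 acceptance (0.44 for scalar blocks),
  and Haario-style empirical-covariance shaping of every multivariate
  block, engaged after 200 burn-in draws and re-estimated from the second
  half of burn-in so the transient does not pollute the covariance.  All
  adaptation freezes at the end of burn-in, so the retained chain is a
  genuine Markov chain with the posterior invariant.
* Because mean(x) > 0, the surface level rides a long posterior ridge
  against the intercept, and naive blocking mixes that direction very
  slowly.  The sampler reparameterizes phi = b + phi~ with phi~ summing
  to zero: the global slope b joins the alpha block (whose shaped
  covariance learns the intercept–slope correlation and proposes along
  the ridge) and phi~ block proposals are re-centered.  The map is linear
  and the ICAR prior level-invariant, so the posterior over phi is
  untouched; only the exploration changes.  The joint block then handles
  the residual spatial-confounding directions that couple alpha with
  individual cells.  On the reference recovery study this raised the
  effective sample size of the slowest direction by roughly an order of
  magnitude.
* Initialization: intercept at log(mean count), everything else at zero,
  scales at 1.  A non-finite initial posterior or a block that accepts
  nothing after adaptation aborts with diagnostics.

Point estimates are posterior means; intervals are equal-tailed 2.5/97.5
percentile intervals with linear interpolation; a parameter is significant
when its interval excludes zero.  Single-chain diagnostics (the workflow
is one seeded run inspected via traces): effective sample size via the
autocorrelation method, a Geweke-style z comparing the first 10% with the
last 50% using ESS-adjusted standard errors, and lag-1 autocorrelation;
parameters with ESS < 50 or |z| > 3 are flagged.  The default run length
is 15,000 iterations with 10,000 burn-in; the reference experiments use
6,000/3,000, which the recovery checks show is already adequate at their
problem sizes.

## Geoprocessing

* **Point filtering.**  Wetland points below 0.01 ha are treated as
  digitization artifacts; lake and river classes are excluded because
  large open-water bodies inflate cover estimates for terrestrial fauna.
* **Cover density.**  Area-weighted kernel density at cell centers with a
  100 km search radius on 10 km cells; the default kernel is the quartic
  (biweight), the common choice of desktop GIS density tools, normalized
  to integrate to 1 over the search disc.  With point weights in hectares
  the density (per km²) is scaled by 100 so a cell reads as "hectares of
  wetland per 100 km² cell".  Mass is conserved to discretization error
  (~1% at these grid ratios).  Count weighting is a flag.
* **Kriging.**  Sparse temperature points are interpolated by simple
  kriging (known prior mean, taken as the data mean unless stated).  The
  variogram is fitted to the binned empirical semivariogram by weighted
  least squares with Cressie weights N_h/gamma²; the default family is
  exponential with covariance psill·exp(−h/range) — "range" is the
  correlation length, not an effective range.  The fitted range is
  bounded below by the first empirical lag: structure below the shortest
  observed separation is unresolvable and would otherwise alias into the
  nugget.  Duplicated locations are averaged before solving.  With zero
  nugget the predictor interpolates exactly; far from data it returns the
  prior mean.
* **Collinearity screen.**  Pairs with |Pearson r| ≥ 0.7 lose one member;
  the later column in input order is dropped (a documented tie-break),
  and zero-variance columns are dropped with a warning.
* **Cover change.**  change = cover(t1) − cover(t2), so positive values
  are losses; percent change is 100·change/cover(t1) with zero-baseline
  cells set to nodata.  (Dividing the baseline by the change — the other
  direction one sometimes sees written — yields a dimensionless reciprocal
  that is unbounded at small changes; this module reports
  change-over-baseline.)
* Rasters are ESRI ASCII grids (plain text, nodata −9999, arithmetic only
  between co-registered grids, nodata-propagating).

## The synthetic generator

The generator mirrors the model's own data-generating story, giving every
downstream check an exact truth:

* **Covariates** are Gaussian-smoothed white noise with a stated range
  (default 30 km on 10 km cells), standardized to mean 0, sd 1.  The
  noise is simulated on a grid padded by four smoothing lengths and
  cropped, because naive edge handling inflates boundary variance
  severalfold and produces spurious extremes (large enough, through
  exp(eta), to destroy count simulations).  Smoothed noise is cheaper
  than exact GP simulation and induces the autocorrelation and
  collinearity regimes the tests need, which is all that is asked of it.
* **Wetland cover** is exp(0.5·field) of such a field: positive and
  right-skewed, mean ≈ 1.1, like area-weighted cover densities.
* **Regions** come from k-means on site coordinates followed by
  contiguity repair (minor disconnected fragments merge into the neighbor
  they touch most), producing watershed-like contiguous blocks of unequal
  size.  Region effects are drawn from the ICAR restricted to its
  sum-to-zero subspace (eigendecomposition of D−W, sampling on the
  positive-eigenvalue directions) — the standard device for simulating
  from an intrinsic prior, and exactly the identifiable component the
  sampler works in.
* **Counts** are Poisson(exp(eta)); configurations implying exp overflow
  (eta > 700) are rejected at generation, matching the likelihood's own
  guard.

What the generator does *not* emulate: irregular coastlines and peninsular
boundary shapes (spatial models are known to behave worse there),
temporally mismatched layers, and the error structure of real range maps
and inventories.  Passing recovery tests therefore demonstrate that the
machinery is correct under the model's own assumptions, not that those
assumptions hold for any particular national dataset.

## Reference experiments and their sizes

All live in `wetland_svc.experiments`, are fully seeded, and are the
package's own study conditions:

* **Quadrature gates.**  Intercept-only model (200 sites at rate 5):
  posterior mean/SD of the intercept vs 1-D deterministic quadrature,
  agreement within 3 Monte Carlo standard errors.  Single-cell/no-random-
  effect model (150 sites, intercept + covariate + wetland slope): vs 3-D
  grid quadrature (61³ nodes on a Laplace-centered grid), same criterion.
  These are the primary sampler-correctness gates — the reduced posteriors
  are computed entirely outside the sampler code path.
* **Surface recovery.**  2,500 sites (50×50), a 6×6 knot grid aligned
  with a three-band truth (−0.5 / 0 / +0.5 on vertical thirds), region
  effects at tau² = 0.1, 10 seeds at 6,000/3,000 iterations: sign
  agreement of the posterior-mean surface ≥ 90% in |truth| = 0.5 cells
  and 95%-interval coverage of cell truths ≥ 85%, pooled.
* **Calibration.**  50 replicates at 400 sites (2×2 surface), shortened
  chains (2,000/1,000): empirical coverage of the fixed-effect intervals
  within [88%, 100%].
* **Diagnostics calibration.**  An AR(1) chain with rho = 0.9 must show
  ESS/N in [0.03, 0.09] (theory (1−rho)/(1+rho) ≈ 0.0526); i.i.d. chains
  must pass the Geweke check in ≥ 95% of 100 seeds.
* **Determinism.**  The full simulate → preprocess → fit → summarize
  pipeline run twice with one seed must produce byte-identical chain and
  product files.

`scripts/acceptance.py` recomputes all of these plus the geoprocessing
identities and a Moran permutation test (999 permutations, one-sided for
positive autocorrelation) showing that a no-random-effect fit leaves
spatially dependent deviance residuals when the simulated regional
structure is finer than the coefficient surface can absorb.

## Numerical choices and limitations

* log(y!) uses the log-gamma function and is kept in the likelihood so
  values are comparable across models; eta > 700 raises rather than
  overflowing (the sampler maps such proposals to −inf).
* Ties and conventions are fixed and documented rather than configurable:
  half-open cells, row-major-i-fastest coefficient order, drop-the-later
  screening, class codes +1/0/−1 with −9999 nodata.
* The surface is reported on kept cells only; no extrapolation into
  trimmed cells.
* Single-chain inference only: no multi-chain R-hat, no HMC.  The Geweke
  and ESS checks are necessary, not sufficient, convergence evidence —
  as is true of any single-chain workflow.
* Proposal adaptation uses acceptance-rate targets that are asymptotic
  optima for Gaussian targets; heavy-tailed posteriors (tiny counts,
  near-empty cells) may mix below nominal efficiency.  The trimming rule
  (≥ 1 site per kept cell) intentionally leaves such weakly informed
  cells in the model, where the CAR prior shrinks them toward neighbors.
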