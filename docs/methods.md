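# Methods

## Model

The mapped quantity is aboveground biomass (AGB, Mg/ha) on a 30 m grid.
The estimation model is regression kriging: a trend `m(x)` fitted on
plot-level AGB against 12 raster covariates, plus ordinary kriging (OK)
of the trend's training residuals,

    AGB_RK(s) = m(x(s)) + Σᵢ wᵢ rᵢ ,   Σᵢ wᵢ = 1 ,

with residuals `rᵢ = yᵢ − m(xᵢ)` at the training plots only; held-out
plots never inform the residual surface. Two trend models are fitted
side by side — a bagged regression-tree ensemble (RF) and a radial-kernel
support-vector regressor (SVM) — giving four surfaces (RF, SVM, RFRK,
SVMRK) that are compared on the same held-out plots.

Assumptions: the residual field is second-order stationary and isotropic
(one variogram describes it everywhere); plot AGB is a point observation
of the cell containing the plot (no footprint averaging); biomass is
nonnegative, so negative predictions and composed values are clamped to
zero with counts logged.

## Plot biomass

Tree AGB (kg) is `exp(β₀ + β₁ ln DBH_cm)` with species-group constants
(CE −2.0336/2.2592, HH −2.0127/2.4342, Pine −2.5356/2.4349, SH
−1.9123/2.3651), valid for DBH ≥ 2.5 cm; smaller trees are rejected
(the model's stated domain) rather than silently dropped.

Expansion to trees/acre: fixed-radius plots use 1/area; prism plots use
`BAF / (0.005454 · DBH_in²)`. **Unit note:** 0.005454 is the US
forestry basal-area constant for DBH in *inches*, while the allometry
takes DBH in cm. DBH is stored in cm everywhere and the prism formula
converts internally (÷2.54). Per-acre kilograms become Mg/ha via
2.4710538 acre/ha and 1000 kg/Mg.

## Variograms and kriging

The empirical semivariogram is the Matheron estimator on distance bins
(default 15 right-closed bins up to half the maximum pairwise distance;
empty bins dropped, each retained bin centered at its mean pair
distance). Parametric models use the effective-range convention:
exponential `γ = n + s(1 − e^{−3h/r})`, gaussian
`γ = n + s(1 − e^{−3h²/r²})`, spherical exact at `r`; `γ(0) = 0` with
the nugget as the `h → 0⁺` limit. Fitting is weighted least squares
with `N(h)/h²` weights (trust-region, bounds `n, s ≥ 0`,
`r ∈ (0, 2·max_lag]`, four starting points, best weighted SSE kept).
A minimum of 30 points is required for an empirical variogram (override
`min_points` for didactic cases) and 4 bins for a fit.

OK solves the augmented system `[[Γ, 1],[1ᵀ, 0]]` with a Lagrange
multiplier (internal state); predictions are `Σ wᵢ rᵢ` and kriging
variances `Σ wᵢ γ(h_{i0}) + μ`, floored at 0 against roundoff. Exactly
coincident points are averaged first (the system is singular
otherwise). Kriging is global — one factorization, all cells — up to
2,000 points; beyond that a nearest-k neighborhood (default k = 64)
solves one small system per cell. Tests and the default study scale run
global, where OK is an exact interpolator for zero nugget.

## Trend models

Both learners are commodity components delegated to scikit-learn behind
a fixed interface. RF: 500 trees, one-third of predictors per split,
unlimited depth, out-of-bag R² recorded. SVM: predictors standardized,
radial kernel, 5-fold cross-validated grid over cost {0.25, 1, 4, 16}
and kernel width {0.25, 1, 4}/p around the 1/p heuristic; constant
columns dropped with a warning. These defaults are the conventional
regression choices; no tuning beyond the stated grid is performed.

Variable importance uses one procedure for both model kinds: the mean
relative increase in MSE (in %) over repeated shuffles of one predictor
column, i.e. the %IncMSE idea applied identically to RF and SVM rather
than two package-specific trackers. Shuffle streams are seeded per
predictor *name*, so scores are invariant to column order.

## Evaluation

On held-out plots: `R² = 1 − SSres/SStot`, `RMSE = √(mean e²)`,
`MAE = mean |e|`, `bias = mean e` with `e = estimate − observation`;
population (divide-by-n) conventions throughout, which makes
`RMSE² = bias² + var(e)` exact. `RI = (RMSE_base − RMSE_RK)/RMSE_base`,
reported as a percentage to two decimals; negative RI means kriging
hurt. R² is reported as NaN when the observations are constant.

## Synthetic landscapes

The generator emulates the statistical structure the method assumes,
not the physics of any sensor:

- six spectral bands, canopy cover, elevation and canopy height are
  independent smoothed Gaussian fields min-max rescaled to plausible
  ranges (reflectance sub-intervals of [0, 1], CC 0–100%, DEM
  100–500 m, height 2–28 m); NDVI/MSAVI/EVI are recomputed from the
  synthetic bands, never drawn independently;
- truth AGB = intercept + Σ βₖ·covariateₖ + GRF residual + white noise,
  clamped at 0. Defaults: β = 3.0 Mg/ha per m of canopy height, 0.3 per
  % canopy cover, 30 per NDVI unit — a pine-belt-like mean near
  70 Mg/ha; residual variogram exponential, nugget 0, partial sill
  400 (Mg/ha)², range 300 m (10 cells); noise sd 10 Mg/ha. The residual
  sill is 4× the noise variance: a strongly autocorrelated regime in
  which residual kriging has signal to recover;
- land cover marks exactly the configured non-forest fraction (default
  10%) by ranking a smooth field, so masking arithmetic is exact;
- plots (default 300 on a 100×100 grid) sit at forest cell centers,
  sampled uniformly without replacement; real plot networks are
  typically clustered, which this default does not emulate;
- tree lists are built per plot by drawing DBH from a lognormal
  (median 20 cm, log-sd 0.35) and species from a pine-dominated mix
  (10/20/55/15% CE/HH/Pine/SH), choosing the tree count from the mean
  per-tree contribution, then solving a multiplicative DBH scale by
  Brent root finding (DBH floored at 2.5 cm) so the allometric
  recomputation matches the sampled AGB within 1%. Prism plots cannot
  represent targets below one floor-diameter tree (~3.4 Mg/ha at
  BAF 10); such plots fall back to the fixed-radius design.

Gaussian fields come from exact dense Cholesky factorization for grids
up to 4,096 cells and FFT circulant embedding beyond (exact when the
embedded covariance is positive semidefinite; negative eigenvalues are
clamped and logged — for the families and ranges used here the clamped
mass is negligible). Both are deterministic under a seed; all generator
randomness flows from one root seed via `SeedSequence` spawning.

Passing tests on these landscapes show that the pipeline's arithmetic,
bookkeeping and geostatistics behave as specified under known
structure. They do not show that any particular accuracy level carries
over to real inventories, whose residual fields need not be stationary
or isotropic and whose covariates carry sensor artifacts absent here.

## Problem sizes and numerics

The default experiment scale is a 100×100-cell grid with 300 plots
(240 train / 60 test), where a full four-model run takes a few seconds;
replicate experiments use 20 such landscapes, and variogram-recovery
experiments use 60×60 grids with 800 sampled points. CSVs are written
with full float precision and read back with round-trip parsing, so a
pipeline re-run from its own artifacts is bit-identical — tree-ensemble
fits can otherwise flip splits on 1-ulp response differences.

## Known limitations

- No co-kriging, universal kriging, anisotropy or block kriging; no
  plot-footprint weighting or neighborhood averaging at extraction.
- The trend learners' residuals at training plots partially absorb the
  autocorrelated signal (in-bag memorization in RF especially), which
  shrinks the fitted residual sill relative to the generating one; the
  composed surfaces still improve held-out RMSE, but the fitted
  variogram parameters underestimate the latent field's.
- Reported metric formulas follow the standard definitions; source
  material sometimes prints corrupted variants of R²/RMSE (an R²
  numerator that collapses to the denominator, an RMSE without its
  root), and the RMSE values in Mg/ha make clear the standard forms are
  what is actually computed.
- GeoTIFF output carries pixel scale, tiepoint and nodata tags plus
  band names, but no CRS key directory; grids are treated as already
  co-registered in a shared projected system, and reprojection or
  mosaicking is out of scope.
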