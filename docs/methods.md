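# Methods

This document records the statistical model, the estimation algorithm, the
synthetic-data generator, and the numerical conventions the package commits
to. Everything here is implemented and tested; no empirical claim is made
about quantities the package does not compute.

## 1. Surveillance quantification

**Grid.** A square grid of `cell_size` (default 200 m) cells over a planar
metric extent. Cell `(i, j)` (row, column, from the lower-left origin) covers
the half-open square `[x0 + j·c, x0 + (j+1)·c) × [y0 + i·c, y0 + (i+1)·c)`;
points on the global top/right boundary are assigned to the last row/column
so the closed extent is covered. Points outside the extent are an error, not
a silent drop.

**Severity and classification.** Each tube carries an ordinal severity scale
0–3. Per cell and wave the *maximum* tube scale is taken. With `s1, s2` the
two wave maxima (either possibly absent):

- **SIRH** iff `s2 > s1` or `s1 = s2 = 3`;
- **USIRL** iff `s2 < s1` or (`s1 = s2 ≠ 3`);
- **undefined** iff either wave is unsampled.

The three outcomes partition all 25 pairs (including absent) as 7 SIRH,
9 USIRL, 9 undefined. Wave-2 tubes inherit their cell's label as the binary
response `y` (1 = SIRH); tubes in undefined cells are excluded and counted.

## 2. Covariates

**Five-level land use.** Two polygon layers (years A and B) are overlaid at
each tube position. If the categories agree the tube gets that category
(agriculture, transportation, artificial, natural); if they differ it gets
the fifth level, **change**. Natural land cover is the dummy reference in
all models. Points on shared polygon boundaries are resolved by the fixed
priority transportation > artificial > agriculture > natural.

**Road distance.** Euclidean point-to-segment distance to the nearest road
*centerline* (an STRtree-indexed union of polylines). A consequence worth
noting: tubes in the transportation category (a buffered corridor around the
centerlines) have a small positive median distance, about half the corridor
width, not zero.

## 3. Risk models

All three models are binomial with logit link for `P(y = 1)`, fitted on the
tube-level table `(y, landuse5, road_dist, x, y_coord)`:

- **GLM** (9 coefficients): intercept + 4 land-use dummies + linear
  `road_dist` + linear `x`, `y_coord` and the product `x·y_coord`. Linear
  columns are standardized internally for conditioning; reported odds ratios
  for the dummies are unaffected.
- **GAM1**: dummies + `f(road_dist)` (univariate P-spline, basis dimension
  k = 10) + `f(x, y_coord)` (tensor-product P-spline, marginal dimension 6).
- **GAM2**: dummies + one factor-by distance smooth per land-use level
  (five smooths; each built on the level's own rows, zeroed elsewhere) + the
  same tensor smooth.

### P-spline construction

Cubic B-spline bases on *uniform, unclamped* knots (the Eilers–Marx layout):
the base interval is `[min(x), Q_0.995(x)]` — the right end capped at the
99.5th percentile because road distances are right-skewed — with knots
extended three uniform intervals beyond each end and polynomial extension
outside. The penalty is the second-order coefficient-difference form `DᵀD`.
Uniform spacing is essential: it makes the Greville abscissae equally
spaced, so coefficient vectors linear in the index represent exactly the
linear functions of the covariate, and the penalty null space is
{constant, linear} (for the tensor product with its two marginal Kronecker
penalties: the bilinear surface `1, x, y, xy`). That is what makes the three
models nested — the GLM's linear terms span the smooths' penalty null
spaces — and what makes the λ → ∞ limit of each GAM collapse onto the GLM
fit (verified to 1e-6 in fitted probabilities).

Each smooth is made identifiable by the sum-to-zero constraint over its
training rows, absorbed by a Householder null-space reparameterization
(basis dimension drops by one). Factor-by smooths are centered over their
level's rows only, so they coexist with the level's dummy.

### Estimation

Penalized IRLS (PIRLS): at each step solve
`(XᵀWX + S_λ) β = XᵀW z` (Cholesky) with working weights `w = μ(1−μ)` and
working response `z = η + (y−μ)/w`, with step-halving so the penalized
deviance never increases. Convergence: `|Δ pdev| < tol·(|pdev| + 0.1)` with
`tol = 1e-8` (100 iterations max). At convergence:

- covariance `V_β = (XᵀWX + S_λ)⁻¹` (Bayesian/ridge form);
- per-coefficient EDF = diag of `(XᵀWX + S_λ)⁻¹ XᵀWX`, summed per term;
- deviance `D = −2 Σ [y log μ + (1−y) log(1−μ)]` (Bernoulli saturated
  log-likelihood 0), so `AIC = D + 2·EDF`.

### Smoothing-parameter selection

GCV score `n·D / (n − EDF)²`, minimized over `log₁₀ λ ∈ [−6, 6]`
coordinate-wise (one coordinate per penalty; GAM2 has 7) by golden-section
search, two sweeps, warm-started between evaluations. If a coordinate's
objective is numerically flat the smallest λ in the box is taken (least
smoothing) and the event is logged. The final model is refitted at the
selected λ from a cold start so the reported fit is independent of the
search path.

### Inference

- **Parametric terms**: odds ratio `OR = exp(β)`, delta-method standard
  error on the OR scale `SE(OR) = OR·SE(β)`, so `z = β/SE(β) =
  log(OR)/(SE(OR)/OR)`; two-sided normal p-values.
- **Smooth terms**: Wald `χ² = βₜᵀ Vₜ⁻ βₜ` with the covariance block's
  eigendecomposition truncated at rank `round(EDF)`; reference χ² with that
  many degrees of freedom. Terms with EDF < 0.5 are reported but not tested.
- **Nested comparison (ANOVA)**: `Δdf = ΔEDF`, `χ² = ΔD`, and the F-variant
  `F = (ΔD/Δdf)/φ` with `φ = 1` on `(Δdf, n − EDF_big)` degrees of freedom.
- **Component decomposition**: the linear predictor splits exactly (to
  machine precision) into intercept + land-use + distance + spatial
  contributions; risk maps export all four (`lp0, lp_landuse, lp_dist,
  lp_spatial`).

### Distance thresholds

For a category, the fitted `P(SIRH)` is scanned along road distance at 1 m
resolution (other covariates held at the category level and the training
coordinate means); `d*` is the largest distance such that the curve stays
≥ p₀ on the whole of `[0, d*]` (contiguous from zero — later re-crossings
are ignored). On the analytic curve `logit P(d) = 1 − d/100` with p₀ = 0.6
this gives the closed form `d* = 100·(1 − ln 1.5) ≈ 59.45 m`, used as an
exact oracle for the scanning logic.

## 4. Synthetic-data generator

**Landscape.** Voronoi patches of `n_patches` seeded points, clipped to the
extent and deterministically ordered; categories assigned by target area
shares (defaults: natural 0.522, agriculture 0.211, artificial 0.104,
transportation 0.056). A square road lattice (spacing 500 m) is overlaid and
its 12 m buffer corridor becomes the transportation category. The year-B
layer is produced by greedily relabelling patches until a target changed-area
fraction (default 0.107 ± 0.02) is reached, with a configurable share of
conversions taken out of natural land (default 0.616, "development-related").
Layers round-trip exactly through GeoJSON.

**Survey.** 1–2 tubes per cell, wave-2 positions jittered within the cell.
One representative wave-2 tube per cell carries the covariates; the cell's
SIRH label is a Bernoulli draw from an explicit true model (log-odds =
intercept + category offsets + optional distance curves + optional smooth
spatial field), then converted to a severity pair drawn uniformly from the
label-consistent set, so classifying the pair recovers the label exactly.

**Table-level simulator.** For replicate studies a faster generator draws
the covariates directly — categories i.i.d. from the surveillance frequency
mix (transportation 0.262, agriculture 0.252, natural 0.250, change 0.172,
artificial 0.063), distances uniform, coordinates uniform — and `y` from the
same true-model interface.

**Seeds.** A single integer seed expands into independent per-stage
substreams via `SeedSequence([seed, crc32(stage)])`; all derived seeds are
below 2³¹.

## 5. Problem sizes and replicate counts

Replicate studies in the test suite and the acceptance script use sizes
chosen by this package to balance statistical resolution against a
single-CPU time budget: odds-ratio recovery at n = 6918 tubes (the scale of
a real island-wide survey) over up to 200 replicates; AIC-ordering studies
at n = 2500 with category-specific distance curves and a spatial sine field;
threshold recovery at n = 3000 with the transportation effect constructed to
cross P = 0.6 at 350 m. The full suite runs in about 3 minutes.

## 6. Limitations

- The engine is specialized: binomial/logit only, second-order penalties
  only, dense linear algebra (design matrices up to a few hundred columns).
- GCV is coordinate-wise over at most a few penalties with two sweeps; it is
  not a global optimizer, and λ values are only resolved to ~0.1 on the
  log₁₀ scale (the final cold-start refit makes results reproducible).
- The truncated-rank Wald test for smooths is a pragmatic approximation; its
  type-I rate is verified empirically for univariate smooths only, and its
  power for high-EDF tensor terms at small n is limited.
- The synthetic landscape is a stylized stand-in (Voronoi patches, lattice
  roads); it reproduces composition and change fractions, not real spatial
  autocorrelation structure.
- Distances are planar Euclidean meters; no geodesy, no CRS handling beyond
  "a projected metric system".
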