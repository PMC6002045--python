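# Methods

This package implements a presence-only climatic-suitability analysis for a
pest–host pair: maximum-entropy distribution models for each species,
model selection over a feature-class × regularization grid, thresholding of
continuous suitability into classes, and an overlay of the two species'
class maps that yields risk levels and area-change statistics between a
current and one or more future climates. This note records the model, the
parameters that matter, the numerical choices, and what the synthetic data
generator does and does not establish.

## The model

Given presence points x₁…x_m and a background sample of landscape cells,
the fitted object is the Gibbs density over the background

    q_λ(x) ∝ exp(λ · f(x)),

estimated by maximizing the L1-penalized presence log-likelihood

    (1/m) Σᵢ λ·f(xᵢ) − log Z_λ − Σⱼ βⱼ |λⱼ|.

This is the standard convex dual of maximum-entropy density estimation
subject to relaxed moment constraints |E_q[fⱼ] − f̄ⱼ| ≤ βⱼ. The feature
basis f is built from the covariates by class: linear (L), quadratic (Q),
pairwise products (P), step/threshold (T) and hinge (H). L, Q and P are
computed on the min–max normalized covariate z = (x − min)/(max − min), so
the fitted suitability surface is exactly invariant to positive affine
rescaling of any input variable (°C vs °F); T and H use knots equispaced on
the training range (default 20 per variable per direction, 2 × for hinges
because both orientations are generated). All feature columns are further
rescaled to [0, 1] by their training bounds, and those bounds are stored in
the model for projection.

Penalties follow the familiar schedule βⱼ = rm · c(class, m) · sⱼ/√m with sⱼ
the presence-sample standard deviation of feature j, floored at 10⁻³ so a
feature constant across presences still carries a penalty; c interpolates on
the presence count m ∈ [10, 100] (L/Q: 1.0 → 0.05, T: 2.0 → 1.0) with P =
0.2 and H = 0.5 fixed. `rm` is the user-facing regularization multiplier.

### Fitting

λ is split into positive and negative parts, turning the non-smooth
penalized problem into a smooth bound-constrained one solved by L-BFGS-B
(projected-gradient tolerance 10⁻⁸, relative-reduction test disabled so the
optimizer does not quit on a flat stretch). Convergence is judged by the
KKT conditions of the original L1 problem, not the optimizer's status code;
a violation above 10⁻³ raises, between 10⁻³ and success it warns. The
presence rows are added to the background for the partition function (the
field's usual convention). This is not cosmetic: without it the objective is
unbounded whenever the presence feature mean lies outside the convex hull of
the background features, which genuinely occurs on strongly separated data;
with it the objective is bounded below by log m for any penalty.

### Output transform and projection

Raw output is q_λ normalized over the training background (it sums to 1
there). The reported suitability is the logistic transform
s = e^H·raw/(1 + e^H·raw), with H the entropy of the fitted raw
distribution; cloglog is available by flag. Projection to another climate
supports three extrapolation policies: `none`, `clamp` (covariates truncated
to their training range before feature evaluation), and `fade` (clamp, then
subtract the absolute difference between clamped and unclamped linear
predictors, rescaled into [0, 1] by its maximum over the projection, floored
at 0). The exact damping formula used by the original GUI is not published;
this linear-predictor-difference form is documented here as this package's
definition. Cells inside the training envelope are identical under all
three modes. Each suitability map carries per-cell counts of out-of-range
covariates as clamp diagnostics.

### Importance measures

Percent contribution is path-dependent in every implementation; here it is
defined by re-tracing the fit with cyclic proximal coordinate ascent from
λ = 0 and crediting each increase of the penalized objective to the
variable(s) owning the updated feature (products split evenly), normalized
to 100. Because of that path dependence, permutation importance — the drop
in training AUC when one variable's values are permuted jointly across
presences and background, averaged over seeded permutations, normalized to
100 — is reported alongside and is the primary measure. The jackknife
refits each variable alone and each variable excluded (2k + 1 fits) and
reports unpenalized training gain, (1/m)Σλ·f(xᵢ) − log Z + log n_bg, i.e.
the improvement over a uniform background model.

## Evaluation and selection

Candidates are the Cartesian product of feature-class sets and
regularization multipliers (study-faithful defaults: {LQPH, LQPTH, LQH,
LQP, LH, LQPT} × {1.0, 1.5, 2.0}). Presences are partitioned into k
balanced random folds (default 10); the background is reused whole in every
fold, since no background-splitting rule is standard. Per fold we record
the test AUC (rank-sum estimator, ties 0.5) of held-out presences against
the background and the test omission rates at two training thresholds: the
training minimum (0%) and the lower empirical 10th percentile (no
interpolation; omission counts test scores strictly below the threshold).
Under iid continuous scores these have nominal values 0 and 0.10, which is
what makes them calibration checks rather than mere descriptive statistics.
Candidates are ranked by mean OR10 ascending, then OR0 ascending, then mean
AUC descending — omission calibration first, discrimination last.

## Thresholding, classes, overlay

The binarization threshold t maximizes test sensitivity plus specificity
(MTSPS) over candidate thresholds at midpoints of adjacent distinct pooled
scores, ties resolved toward the smallest t; it is computed from the pooled
held-out fold predictions of the winning candidate against the background
scores of the final refit. The suitable range [t, 1] is split into three
equal-width bins — low, medium, high (half-open below, closed at 1; a value
exactly at t is low) — a parameter-free default, overridable with explicit
bounds, since no published rule defines the interior cut points. Host
cells of medium or high class form the "optimal" mask; inside it the pest's
class becomes the risk level (unsuitable → no risk, low → low risk, …), and
outside it cells are reported as outside-optimal. Future slices are
classified with the current-climate threshold and bounds so that per-class
areas are comparable, and change is reported as
(future − current)/current × 100 (positive = extension, negative =
shortening), undefined (flagged) when the current area is zero.

Areas are latitude-aware by default: a cell in row r contributes
(cell_size·π/180·R)²·cos(lat_r), R = 6371 km on a spherical Earth; a planar
cell-count mode is available by switch, since the original area computation
is not documented. All distances (thinning, kernels) are great-circle
haversine distances on the same sphere.

## Occurrence handling

Ingestion collapses exact duplicate coordinates and drops rows with
out-of-range or non-numeric coordinates, counting both. Thinning enforces a
strict minimum pairwise distance (default > 10 km) by repeatedly deleting
the point with the most neighbours inside the cutoff (ties uniform at
random) until no violation remains, repeated over randomized restarts
(default 10) with the largest retained set returned. On clouds of ≤ 12
points this greedy rule stays within one locality of the exhaustive optimum
in 100 seeded trials. The sampling-bias surface is a Gaussian kernel
density of the presences over unmasked cell centres (bandwidth not stated
in any source; default 200 km, configurable and logged), normalized to sum
to one; background cells are drawn with replacement proportional to it
(study-faithful n = 50,000), or uniformly when no bias surface is given.

## Predictor screening

Pairwise Pearson correlations are computed over all unmasked cells by
default (the population used in the original screening is unstated; an
occurrence-cell option exists). The retained set is built by a greedy scan
in an explicit priority order, keeping a variable iff |r| < 0.75 against
everything already kept; |r| ≥ 0.75 excludes. The priority list is the
auditable stand-in for "biological relevance" judgements; its default puts
the six variables of the published final models (bio1, bio2, bio7, bio12,
bio14, bio15) first.

## The synthetic study system

Real inputs (occurrence databases, global climate layers, GCM projections)
are not bundled; the generator produces inputs with the statistical
structure the pipeline assumes, with a known truth to recover:

* climate: a temperature-like layer (`bio1`) with a linear latitudinal
  gradient spanning ≈ 2–26 °C plus smoothed Gaussian noise, clipped to
  [0, 30]; a precipitation-like layer (`bio12`) with longitudinal wet/dry
  bands filling ≈ 0–3000 mm; optional extra layers of rougher pure noise
  (smoothing σ = 1 cell vs 3 for the drivers) that by construction carry no
  information about the truth — the rougher texture keeps them from
  mimicking the latitudinal trend by chance in a finite window, so
  importance and jackknife tests have known losers;
* truth: s(x) = exp(−(T − T_opt)²/(2σ²)) · h/(h + P), unimodal in
  temperature and strictly decreasing in precipitation. Defaults T_opt =
  23.8 °C and σ = 3.8 °C mirror the occurrence-sample mean and SD of annual
  mean temperature for the pest this package was built around (20.1 °C for
  the host); the precipitation half-saturation h = 150 mm and the band
  amplitude were chosen so the truth's intrinsic presence-vs-background
  discriminability (AUC ≈ 0.89) matches the ≈ 0.90 cross-validated AUC the
  real study system exhibits;
* the warm edge of the window sits just above T_opt, so a uniform +2 °C
  perturbation moves almost the whole window toward the optimum and mean
  true suitability rises — the projection regime the overlay stages are
  meant to exercise;
* presences: cells drawn with probability ∝ truth (× an optional bias
  field), jittered uniformly within the cell so coordinates are distinct
  and the thinning contract is exercised; a "future" slice shifts
  temperature layers additively and scales precipitation layers.

What passing on this generator shows: the estimator recovers a known niche
optimum (±1 °C at n = 500 with LQ features), discriminates presences from
background at the intended level, ranks the informative variable first, and
moves projections in the right direction under warming. What it does not
show: robustness to the covariance structure of real bioclimatic variables
(19 strongly cross-correlated layers), to real observer bias, to coordinate
error beyond sub-cell jitter, or to niche shapes outside the
Gaussian-times-saturation family. One caution specific to synthetic,
unbiased sampling: weighting the background by a presence-kernel density
cancels genuine niche signal (the background then matches the presence
climate); the quick-start preset therefore uses a bandwidth broad relative
to its window (1,500 km on a ≈ 3,500 km window), and a uniform background
is available via `bias=None`.

## Problem sizes

The default test-suite and quick-start sizes are deliberately small: a
32×32 one-degree window, 200 presences and 2,000 background points per
species, three candidate feature sets at one RM, 3 folds, and 10 hinge
knots per direction — a full two-species run in well under a minute. The
numbered analysis drivers use a 40×40 window, 500 presences, 5,000
background points, the full 18-candidate grid at 5 folds and 8 knots
(minutes, single CPU). The study-faithful defaults (50,000 background
points, 10 folds, 20 knots) remain the package defaults for real inputs.

## Known limitations

* No resampling or reprojection: input rasters must already share their
  grid; mismatches are errors by design.
* Categorical covariates are not supported (the target analysis used none).
* Percent contribution is algorithm-defined (coordinate-path credit) and
  will not numerically match other implementations; permutation importance
  is the comparable measure.
* The fade damping formula is this package's documented definition, not a
  reverse-engineered replica of the original GUI's.
* Bit-compatibility with the original MaxEnt software's outputs is a
  non-goal; agreement is at the level of the objective being optimized.
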