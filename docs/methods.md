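# Methods

This note documents the models, the synthetic data they are exercised on,
the numerical choices, and the limits of what the test-suite demonstrates.

## Problem setting

Presence-only species distribution modeling from opportunistic collar
telemetry: locations tell us where animals were, not where they were
absent, so suitability is estimated by contrasting presence environments
with the available environment (background). The package implements a
consensus of two model families fitted at two spatial scales — one
statewide model and one model per management unit (fitted on the unit
buffered by 20 km, trimmed back to the unit when mosaicking) — because
single models and single scales are each known failure points of
presence-only inference.

## Telemetry screening

Rules, in order: capture and mortality records are dropped; GPS fixes with
a low-quality fix status (default codes `2D`, `failed`; the quality-code
set is configurable because collar vendors differ) or DOP > 7 are dropped;
then whole animals are dropped when younger than 4 years, when no 365-day
window contains >= 30 retained fixes, or when every such window spans fewer
than 3 distinct calendar months. The "12-month window" is a sliding 365-day
window anchored at each fix — stricter and better defined than calendar
years. GPS tracks are then thinned greedily to >= 5 h spacing (keep the
first fix, then the earliest fix at least the interval later); VHF fixes
pass through, since their sampling is already sparse. Fix-level filters run
before animal-level counts so the counts reflect usable locations only.

## Covariates

All operators work on a shared square-cell grid (default 120 m, the
resolution at which home-range-scale conditions are captured):

* Euclidean distance to a class, center-to-center (exact distance
  transform).
* Focal density: share of true cells among cells whose centers fall within
  the window radius (0.5 km "local", 1.5 km "neighbourhood"); edge windows
  are truncated to the grid, keeping the output a true proportion.
* TRI: root-mean-square elevation difference to the eight neighbours;
  boundary cells average the neighbours that exist.
* Shape index `0.25 P / sqrt(A)` per 4-connected patch, P counting every
  edge shared with a different patch, background, or the grid exterior;
  1 for squares, area-weighted mean across patches.
* Contiguity: per patch cell, a 3x3 template score (orthogonal neighbours
  weight 2, diagonals 1) normalized so isolated cells score 0 and fully
  surrounded cells 1, averaged over patch cells within a circular window of
  0.5 km²; the window aggregation is our own reading, as the original
  metric's local-window form is not defined formulaically anywhere we
  could pin down.
* Correlation screen: Pearson |r| >= 0.7 flags a pair (0.7 is the
  conventional cutoff; configurable); zero-variance layers are set aside as
  degenerate.

## Maxent

The model is the regularized Gibbs / infinitely-weighted logistic
equivalence: minimize over coefficient vector lambda

    log Z(lambda) - mean_presence(lambda . f) + sum_j beta_j |lambda_j|,

with Z summed over the background sample. Features per covariate: linear,
quadratic, and forward+reverse hinges with 15 knots per direction at
training quantiles, all scaled to [0, 1] and clamped to training bounds at
prediction time. Product/threshold features are omitted — hinges subsume
thresholds and keep the feature count tractable. beta_j is the published
feature-class default (interpolated on presence count) times the feature's
presence-sample SD over sqrt(n), times a configurable multiplier.

The optimizer is proximal gradient with backtracking line search; the
sufficient-decrease test guarantees the penalized objective is
non-increasing, convergence is a relative objective change < 1e-6, and the
fit errors out rather than returning silently if the iteration budget
(5,000) is exhausted. With the penalty at zero and linear features, the fit
is the Gibbs MLE; parameter-recovery tests drive this route.

Output transforms: raw (sums to 1 over the training background), cloglog
`1 - exp(-e^H raw)` (default — the default of the Maxent version the
workflow standardizes on), and logistic. All are strictly monotone in raw,
so ranking metrics are transform-invariant.

Percent contribution is permutation importance: shuffle one covariate
across the pooled presence+background points, re-evaluate only that
covariate's feature block, record the drop in training gain (mean of 10
shuffles, floored at 0), normalize to 100. We chose this over the solver's
path-dependent per-iteration gain bookkeeping, which is specific to the
sequential-update solver and not reproducible from a converged model.
Reverse step-wise selection: fit all variables, drop contribution <= 1%,
resolve each flagged correlated pair toward the higher contributor, refit;
at most 5 rounds.

Background: 10,000 uniform cell-center draws with replacement (duplicates
allowed, so small regions are handled). The statewide model restricts
sampling to the 95% KDE isopleth of the presences with the reference
bandwidth h_ref; local models do not (within-unit conditions are
comparatively homogeneous, and restricting there would discard the very
contrast the local models exist to capture).

## Mahalanobis

mu and Sigma (denominator n-1) from the presence covariate matrix; Sigma
must be positive-definite (smallest eigenvalue > 1e-10, else the error
names the most collinear column pair). D² is computed via a Cholesky solve,
never an explicit inverse. Suitability is the chi-square(df) upper-tail
probability of D², which is 1 at the centroid and strictly decreasing.

Variable removal: the literature describes PCA-guided iterative removal
without quantifying it. We rank variables by their squared loadings on the
variance-deficit components of the standardized presence matrix — the
"limiting dimension" reading from partitioned-Mahalanobis niche analysis:
combinations of covariates the species holds nearly constant are exactly
the low-variance components at presences, and variables irrelevant to
selection load on components with variance at or above the standardized
average. The loop drops the lowest-ranked variable whenever its share falls
below 5% of the total, stopping at df = 2. We first implemented the more
obvious ranking (squared loadings on the retained high-variance
components) and found it anti-selective on synthetic truth: selection
compresses informative variables into low-variance PCs, so that ranking
consistently scored pure-noise layers highest and removed the most
informative variable first. The exported `pca_contribution` keeps the
high-variance orientation for descriptive ranking; `limiting_contribution`
drives removal.

## Evaluation

* AUC: rank-based, ties counted one half; background points are the
  negative class (true absences are unavailable in this design).
* Continuous Boyce index: 101 overlapping windows of width = suitability
  range / 10 (the conventional moving-window defaults; configurable);
  P/E = presence share over cell share per window; Spearman correlation of
  P/E against window midpoints over windows with E > 0.
* Threshold: the smallest observed score maximizing sensitivity +
  specificity, with `score >= t` meaning habitat — the >= and the
  smallest-maximizer tie-break are fixed so binary maps are
  bit-reproducible.
* TSS = sensitivity + specificity - 1, enforced as an identity on every
  report.

## Consensus, mosaic, categories

The consensus surface is the cellwise mean of all iteration surfaces (both
families, e.g. 10 + 10 per extent); Mahalanobis surfaces enter unrescaled
since both families live in [0, 1] (an optional min-max rescale flag
exists, off by default). The binarization threshold is the mean of the
Maxent iterations' max-SSS thresholds only — Mahalanobis outputs are tail
probabilities whose absolute scale is not commensurate with cloglog
outputs, so its thresholds are not averaged in. Local models are fitted on
buffered units but contribute values only inside their own unit at mosaic
time, making the mosaic independent of processing order and free of
double-coverage ambiguity. Categories are coded 1*local + 2*state
(0 none / 1 local-only / 2 state-only / 3 both); a plain sum could not
distinguish the two single-scale cases. Areas are cell counts times
(cell/1000)², so every percentage in the overlay reports recomputes exactly
from its own printed areas; report percentages round half-up to 2 decimals
while machine outputs keep full precision. Display binning reclassifies a
consensus surface at the deciles of suitability sampled at the presences,
giving ten bins each holding ~10% of presences (up to ties); per-iteration
thresholds are averaged unrounded.

## Synthetic data: what it emulates and what it does not

Covariate fields are Gaussian with exponential covariance (range 2.4 km by
default), synthesized spectrally by circulant embedding — fast, exactly
seeded, and matching the dense-Cholesky oracle on small grids. Land cover
(natural / agriculture / urban / wetland / water) and elevation derive from
thresholded fields, with water below elevation zero so inundation masks
are elevation-driven and nest across sea-level scenarios. Truth
suitability is inverse-logit-linear in three of the six continuous fields
(two of the six are pure noise, standing in for candidate layers with no
habitat signal). Telemetry is a per-animal random walk whose proposed steps
(Gaussian, SD 2 cells) are accepted with probability equal to destination
suitability — a rejection mechanism whose stationary enrichment is known,
which is what the recovery tests rely on. Collars are mixed (30% VHF at
5x sparser schedules, no DOP; GPS with lognormal DOP, median 2, sigma 0.6,
putting ~2% of fixes past the DOP 7 screen), 20% of animals are juveniles,
first fixes are capture events and 15% of animals end in mortality — so
every screening rule is exercised. Units are a seeded k-region Voronoi
partition (default 4).

Defaults simulate 30 animals x 2,200 hourly fixes on a 120x120 grid
(~3 months per track, so the distinct-month rule can pass). The end-to-end
benchmark uses a 200x200 grid, 60 animals and a sharply selective virtual
species (beta = 5, 4, -5; intercept -6, the `STRONG_TRUTH_*` preset):
with milder selection, the AUC ceiling of the *truth surface itself*
against this telemetry sits near 0.75-0.85 — home-range-confined walks
leave suitable but unvisited habitat labeled background — and no model can
beat its own data's ceiling. These sizes keep the full two-scale,
ten-fold, two-family pipeline around five minutes on one CPU.

What passing tests do not show: real telemetry has habitat-dependent fix
failure, seasonal and sex-specific movement, spatial bias from study-site
access, and covariate layers with shared measurement provenance; none are
emulated. The generator validates the machinery and its statistical
contracts, not ecological realism.

## Numerical and I/O choices

Rasters are ESRI ASCII grids with a JSON sidecar for the CRS tag (the CRS
is carried, never interpreted); polygons GeoJSON via shapely; models JSON;
tables CSV. Grids must match exactly (shape, origin, cell size) for any
stack operation; nodata is NaN in float rasters and -9999 in integer
rasters and propagates through averaging and thresholding. All stochastic
stages draw from `numpy.random.default_rng` streams derived from one run
seed; the pipeline writes a SHA-256 manifest so reruns are checkable.
Degenerate inputs fail loudly: empty distance targets, constant rasters in
the Boyce index, singular covariances, non-finite features, unparseable
timestamps (naming the record), units without model outputs at mosaic
time.

## Known limitations

* Pipeline units with fewer than 10 presences abort the run rather than
  borrowing a neighbouring model; choose unit counts the telemetry can
  support.
* Percent contribution is permutation-based and therefore carries Monte
  Carlo noise of a few tenths of a percent near the 1% selection floor.
* The Mahalanobis removal rule is a documented stand-in for an
  unquantified procedure; with few informative covariates and many noisy
  ones its df choice drives the chi-square mapping noticeably.
* The KDE isopleth is raster-based; its polygon export is the union of
  cell boxes, adequate for sampling but not a smooth home-range contour.
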