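# Methods

`sedmap` implements a multiscale workflow for predictive seabed-sediment
mapping from multibeam echosounder (MBES) data: terrain and acoustic
predictors derived at several spatial scales, compositional modelling of
grab-sample grain-size fractions with boosted regression trees (BRTs), and
classified substrate maps with cross-validated uncertainty estimates.  This
note records the model, the conventions and numerical choices behind each
stage, what the synthetic scenes do and do not emulate, and the known
limitations.

## Raster model and focal engine

A `Grid` is a single-band, square-celled, north-up raster with an explicit
nodata mask; all layers of an analysis share one grid geometry (mismatches
raise rather than resample silently).  GeoTIFF I/O stores the cell size,
origin and nodata value in the standard tags (ModelPixelScale,
ModelTiepoint, GDAL nodata) via `tifffile`.

Focal statistics (mean, population SD, min, max) over square windows and
annuli are nodata-aware.  Footprints are decomposed into per-row runs, so
window sums reduce to differences of row-wise cumulative sums; this is
exact to machine precision (the unit tests compare against nested-loop
oracles at 1e-12) and linear in grid size even for the 101x101-cell broad
annulus.  Conventions chosen where common GIS tools differ:

- **Edges** shrink the footprint: the statistic is taken over the in-grid,
  unmasked cells only.  No padding.
- **Annulus membership** is Euclidean centre-to-centre distance d in cell
  units with inner < d <= outer.
- **Masking is absorbing**: a footprint with no unmasked cell yields
  nodata, never zero; and a derivative is nodata wherever its source cell
  is, so the whole candidate stack stays aligned with the survey coverage.
- **Point extraction** is cell-containment (no interpolation), with
  upper-left origin and cell-centre registration.

## Terrain and acoustic attributes

Sixteen multiscale attributes are derived at the native resolution with a
3x3 window of analysis, plus a single-scale distance-from-coast layer.  The
local mean is excluded: it duplicates the bathymetry layer itself.

- **Slope and aspect** use Horn's 3x3 gradient.  Aspect is decomposed into
  eastness = sin(aspect) and northness = cos(aspect) so orientation enters
  models as two continuous predictors; flat cells take (0, 0) rather than
  nodata to keep the pair defined everywhere.
- **RDMV** (relative difference to mean value) is
  (centre - mean)/(max - min) over the 3x3 neighbourhood, 0 when the range
  is zero; it is bounded in [-1, 1].
- **Focal SD** is the population (N) standard deviation, matching common
  GIS focal tools; documented so tests can be exact.
- **Curvatures** come from the Zevenbergen-Thorne 3x3 polynomial fit with
  the conventional GIS x100 scaling: general curvature = -200(D + E),
  profile curvature negative where the surface is convex-up along the slope
  line, plan curvature positive where laterally convex; profile and plan
  are defined as 0 on zero-gradient cells, and all three vanish on planes.
  (Some texts label these units "degrees per metre"; the tool convention is
  1/100 z-units per map unit, which is what is implemented.)
- **BPI** (benthic position index) is centre depth minus the annulus mean,
  with fine radii (1, 20) cells and broad radii (15, 50) cells; positive on
  highs.  Values are kept as floats (no integerisation).
- **Surface area and rugosity** use Jenness's eight-triangle construction
  (triangles from the cell centre to midpoints toward adjacent neighbours,
  Heron's formula).  It is exact on planes - rugosity = 1/cos(slope) - and
  rugosity is >= 1 by construction.
- **VRM** (vector ruggedness measure) is Sappington's 1 - |mean unit
  normal| over 3x3, 0 on any plane.
- **Delta-backscatter** is focal max minus focal min of backscatter (dB),
  the local acoustic heterogeneity.
- **Distance from coast** is the Euclidean distance from each cell centre
  to the coast geometry (polyline or polygon boundary).

Masked or off-grid neighbours in the 3x3 operators are substituted by the
centre value, i.e. the surface is treated as locally flat toward missing
data; an attribute is nodata wherever its source is.

## Multiscale candidate set

The strategy is *derive, then average*: each attribute is computed once at
native resolution, then focal-mean averaged over square windows of 3, 5, 9,
13, 21, 35 and 55 cells - the Fibonacci sequence rounded up when even, a
ladder whose spacing grows geometrically - with window 1 denoting the
native layer.  At 5-m cells this spans analysis scales of 5-275 m.  All
scales live on the native grid (no pyramid resampling), so extraction and
prediction stay cell-aligned.  The BPIs additionally carry an effective
scale of (outer radius x cellsize) x window: 100-5500 m (fine) and
250-13750 m (broad) at 5-m cells.  16 attributes x 8 windows + distance
from coast = 129 candidate layers.  The alternative coarsen-then-derive
design is out of scope.

## Compositional model

Mud, sand and gravel fractions close to 1 and are modelled on the additive
log-ratio (ALR) scale with sand as reference: alr_ms = log10(mud/sand),
alr_gs = log10(gravel/sand).  Base 10 is used throughout because the
back-transform is defined with powers of ten; a base-e forward with a
base-10 inverse would not round-trip.  The inverse is closed-form and
always produces positive fractions summing to 1.

Observed zeros (a size class absent or below laboratory precision) are
replaced by delta = 1e-4 with the nonzero parts rescaled by
(1 - k*delta)/(their sum) - "simple replacement" with re-closure.  The
perturbation of each nonzero part is below k*delta.

Classification follows Long's four-class simplification of the Folk
triangle, driven by gravel percent G and the sand:mud ratio R: mud & sandy
mud (G < 5%, R < 1), sand & muddy sand (G < 5%, R >= 1), mixed sediment
(5% <= G < 80%, R < 9), coarse sediment (G >= 5% and R >= 9, or G >= 80%).
Boundaries are closed on the coarser side; R = +inf when mud = 0.  The
thresholds are those of the cited classification scheme, not free
parameters.

## Boosted regression trees

The BRT contract mirrors the gbm / Elith-Leathwick workflow for Gaussian
responses.  `fit` grows a stagewise ensemble to `max_trees`, selects the
iteration count minimising the k-fold cross-validated deviance (squared
error), and refits on all data at that size.  The report carries percent
relative influence (summing to 100), percent CV deviance explained
(100 x (null - CV residual)/null, pooled over folds against each training
fold's mean), and the training residual deviance at the chosen size.
Everything is deterministic given the config seed: the fold split and each
fold model's bagging stream derive from it.

The engine is scikit-learn's `GradientBoostingRegressor`; gbm's interaction
depth (splits per tree) maps to `max_leaf_nodes = tree_complexity + 1`.
The engine is deliberately swappable - the report fields, not the engine,
are the API.  Degenerate input (constant response) yields a zero-deviance
report with uniform influence rather than an error.

Library defaults follow the tutorial conventions the workflow derives from
(learning rate 0.005, tree complexity 5, bag fraction 0.5, up to 10000
trees, 10 folds).  The bundled experiments, examples and acceptance script
use a faster configuration - learning rate 0.05, 500 trees, 5 folds -
whose CV-selected ensembles reach the optimum well inside the tree budget
on the n=300 sample tables used here; this is the package's desk-scale
choice and every setting remains configurable.

Partial dependence is computed by direct marginalisation: the predictor of
interest is swept over a grid while the other columns keep their empirical
values, and predictions are averaged.

## Scale and variable selection

For each response the pipeline runs:

1. **Screen**: one BRT per attribute on its eight scale columns.  The
   percent influence per column locates the informative scales; the
   *cross-validated* residual deviance of the screen ranks attributes
   (ascending).  Ranking uses the held-out rather than the training
   residual deviance: training deviance at the CV-chosen tree count is
   biased toward attributes whose internal CV happened to pick more trees,
   which in experiments inverted ranks between near-collinear attributes.
   The held-out figure is also the headline deviance the gbm-style
   workflow reports per model.
2. **Filter**: scales contributing >= 10% to their screen survive
   (boundary inclusive).
3. **Prune within**: greedy sweep over an attribute's survivors in
   descending contribution; a scale is kept iff its Spearman |rho| with
   every kept scale of that attribute is < 0.7.
4. **Prune across**: attributes visited in ascending rank; each surviving
   layer is kept iff its Spearman |rho| with every layer retained so far
   (any attribute) is < 0.7.  Pruning is layer-level, so an attribute can
   lose some scales and keep others.
5. **Final fit**: one BRT per response on the retained layers.

Spearman correlation is used for both pruning passes.  Ties in
contribution or rank break toward the finer scale, then alphabetically, so
the procedure is deterministic.  Distance from the coast has one scale: it
skips step 1's multi-scale screen, is ranked by its own single-predictor
fit, and competes normally in step 4.  The two responses are selected
independently.  Every dropped layer carries exactly one reason
(`below_10pct`, `corr_within`, `corr_across`), so the audit trail
reconstructs the retained set.

## Prediction, evaluation and classification

The two fitted models predict ALR values for every cell holding all their
retained layers; the closed-form inverse yields mud/sand/gravel maps that
sum to 1 cellwise, and the Long/Folk classifier produces the four-class
substrate raster.  Interior nodata slivers can be filled before
classification by inverse-distance (1/d^2) weighting from the ring of
valid cells around each gap, with the three fractions renormalised
afterwards; gaps wider than a configurable limit are left open, and
exterior nodata is never invented.  This is a pragmatic, cosmetic stand-in
for natural-neighbour interpolation, adequate for the sliver-filling role
it plays.

The manual k-fold cross-validation partitions samples uniformly at random
(seeded; no spatial blocking), refits both responses per fold, and
back-transforms predictions at withheld sites.  Spearman's rho per
fraction is computed per fold and then averaged, not pooled.  When a layer
stack is supplied, each fold's model pair also predicts full fraction
maps, and their per-cell standard deviation forms model-consensus
surfaces; these derive from the manual folds, not from the engines'
internal CV folds.

## Synthetic scenes

The generator provides fully known study conditions so every stage is
testable without survey data.  Defaults describe a 2 x 2 km coastal scene:
400 x 400 cells at 5-m resolution, a north-south coast at the western map
edge, 300 grab samples.

- **Bathymetry** is a planar offshore trend (-20 m at the coast, -0.035
  m/m eastward) plus Gaussian random fields in three spectral bands:
  cell-scale roughness (20 m correlation length, 2 m amplitude), mesoscale
  bedforms (150 m, 5 m), and basin-scale relief (600 m, 10 m).  The bands
  are deliberate: ladder neighbours of any focal-averaged attribute are
  ~0.95-correlated by construction, and only a surface with distinct
  variance at fine, mid and broad wavelengths makes the analysis scale of
  a predictor statistically identifiable at all - a single-band surface
  would leave every window of an attribute interchangeable.  Fields are
  white noise smoothed with a periodic Gaussian kernel; `correlation
  length` means the practical variogram range (95% of sill), `amplitude`
  the field SD, both verified by FFT-autocorrelation in the tests.
- **Backscatter** is linear in an independent latent coarse-sediment field
  (75 m range) at 5 dB per latent SD, plus 6 dB of white speckle -
  uncompensated MBES backscatter is noisy, and the speckle is what makes
  focal averaging progressively informative.  The gravel/sand response
  below loads on a backscatter layer, which induces the backscatter-
  coarseness correlation seen in real surveys (the generative arrow runs
  from acoustics to sediment rather than the physical direction; the joint
  distribution is equivalent for testing purposes).
- **Truth** ALR fields are linear in standardised stack layers plus
  Gaussian noise at a signal-to-noise ratio of 5.  Both responses load on
  the same three-layer set - broad BPI averaged over 35 cells (175 m),
  native eastness, and backscatter averaged over 9 cells (45 m) - with
  balanced coefficients, and intercepts centring the compositions on a
  sandy shelf (alr_ms = -1.08, alr_gs = -0.88).
- **Grab samples** read the true fractions at uniformly drawn distinct
  cells; mud and gravel below a 1% detection limit are recorded as exact
  zeros and the composition re-closed, reproducing the zero-inflation of
  laboratory grain-size tables.

What the scenes do *not* emulate: acoustic artefacts and survey-line
noise, multi-frequency backscatter harmonisation, anisotropic or
non-stationary seabed structure, depth-biased or clustered sampling,
positional error of grab samples, and any gravel/video integration.
Passing the end-to-end tests therefore shows that the workflow recovers
scale-structured signals under clean, stationary, isotropic conditions
with honest noise - not that it would do so under the artefact load of a
real survey.

## Problem sizes in the bundled experiments

The end-to-end experiments (test suite and acceptance script) use the
default 400 x 400-cell scene with n = 300 samples; recovery statistics run
ten seeds.  Unit and property tests use 20 x 20 grids for oracle
comparisons and 120-200-cell scenes elsewhere - the smallest sizes on
which the broad-BPI annulus and 55-cell windows still fit.  These are the
package's chosen experiment sizes; all of them are parameters.

## Known limitations

- **Attribute ambiguity**: broadly averaged relatives (fine vs broad BPI,
  mean curvature, coarse-scale bathymetry) converge toward the same
  band-pass of the surface and can exceed the 0.7 pruning correlation
  against each other.  When such a proxy out-ranks the generating
  attribute, across-attribute pruning substitutes it; on the default
  conditions this happens in roughly one or two seeds in ten.  This is a
  property of the selection procedure itself, not of the implementation.
- **Scale resolution**: adjacent ladder windows are strongly correlated,
  so a recovered scale is meaningful only to about one ladder step.
- The squared-error loss makes the screens sensitive to the heavy ALR
  tails that zero replacement creates at censored samples.
- Gap filling is not a true natural-neighbour interpolant and should stay
  cosmetic.
- The manual CV is not spatially blocked; with autocorrelated fields its
  statistics are optimistic relative to spatially independent validation.
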