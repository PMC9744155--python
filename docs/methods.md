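# Methods

This note records the models implemented in `noctule`, the defaults and
why they were chosen, what the synthetic data generator does and does not
emulate, and the numerical decisions a maintainer should know about.

## Study design in brief

The pipeline estimates climate-driven habitat suitability for a
wide-ranging forest bat, refines it with terrain and river information,
converts the refined map into an electrical network to locate movement
corridors between populations and toward old-growth forests, and asks
whether populations from different longitudinal sectors occupy separable
climatic niches and how well they are covered by protected areas.

## Occurrence screening

* **Age filter** (`min_year`, default 1970): positively dated records older
  than the cutoff are dropped; undated records are kept, since the filter
  targets known-stale localities.
* **Precision filter** (`max_coord_error_arcmin`, default 2.5): the
  uncertainty implied by a coordinate printed with *d* decimals is taken as
  half the last printed digit, `0.5·10⁻ᵈ` degrees. Records whose implied
  uncertainty exceeds the working raster resolution are unusable for cell-level
  modelling. Explicit precision metadata overrides printed decimals.
* **Deduplication** (`cell_size`, default 2.5 arc-min): one record per
  raster cell, keeping the first encountered.

Filtering is idempotent, and per-rule drop counts are reported. Pairwise
distance statistics use great-circle distances on a spherical earth
(R = 6371.0088 km); a planar option exists because projected workflows
report planar kilometres — over a continental window the two differ by a
few percent, which is why both are exposed.

Longitude groups are half-open on the left break (0.0°E is Central,
15.0°E is East); published group limits repeat their endpoints without a
tie rule, so the half-open convention is this package's choice, with the
last break closed so the easternmost record is not orphaned.

## Niche model

* **Collinearity screen**: iterative VIF elimination with the conventional
  threshold 10, applied as `VIF ≥ 10` (a predictor exactly at the
  threshold goes). VIF is computed from the OLS R² of each predictor on
  the others; exact linear combinations surface as infinite VIF and are
  removed first.
* **Pseudo-absences**: uniform draw without replacement from cells whose
  great-circle distance to the *nearest* presence lies in [130, 250] km.
  The lower bound is the species' maximum recorded daily foraging transit
  (reducing false absences), the upper bound keeps the contrast
  ecologically local. If fewer cells are eligible than requested, all of
  them are returned with a warning rather than sampling with replacement.
* **Case weights**: pseudo-absences weigh 1, presences weigh
  `n_pa / n_presence`, equalizing the class totals.
* **Boosted trees**: scikit-learn's gradient boosting classifier carries
  the model; the R gbm vocabulary maps as interaction depth → `max_depth`,
  minimum node size → `min_samples_leaf`, bag fraction → `subsample`,
  shrinkage → `learning_rate`. Tuning minimizes the cross-validated RMSE
  of predicted probability against the 0/1 label; the CV curve is evaluated
  along the entire boosting path (staged predictions), so one fit per fold
  prices every candidate tree count. Ties break toward fewer trees, then
  smaller shrinkage. CV (default 10-fold; 5-fold at desk scale) is the
  selection criterion throughout; a separate holdout fraction is not used
  for selection.
* **Default grid**: shrinkage {0.01, 0.1, 0.3} × depth {1, 3, 5} × node
  size {5, 10, 15} × bag fraction {0.65, 0.8, 1}, trees up to 20,000. The
  grid is fully configurable (`TuningGrid`); the desk-scale pipeline runs a
  2 × 2 subset with 250 trees so the whole study fits in minutes.

### Evaluation

* **Continuous Boyce index**: 101 moving windows of width = range/10 over
  the suitability axis; per window the predicted-to-expected ratio
  P/E = (presence share)/(background share); the index is the Spearman
  correlation of P/E with the window midpoint. Windows with zero expected
  share are skipped; constant predictions raise an error rather than
  returning a number. Note that with window width = range/10 only ~10
  windows are effectively independent, so under a no-information null a
  single Boyce value fluctuates with sd ≈ 0.3; null behaviour should be
  judged by the mean over replicate draws, which the tests and the
  acceptance script do.
* **Correlogram**: Moran's I per equal-width great-circle distance class
  with binary within-class weights and a permutation p-value (199
  shuffles by default — a conventional count, chosen here). Classes with
  no pairs are reported as missing.
* **Contributions**: normalized impurity (deviance-reduction) importances,
  in percent summing to 100; a permutation-importance alternative is
  available by flag because impurity importances can favour high-cardinality
  or correlated predictors.
* **Interaction**: Friedman's H per predictor pair from centered
  partial-dependence functions on the raw (logit) score over a quantile
  grid (default 50 × 50; tests use coarser grids).
* **Response curves**: brute-force partial dependence on the probability
  scale over each predictor's observed range.

## Projection, MESS, ensemble weighting, reclassification

Projection applies the fitted model cell-wise; nodata propagates, and a
missing predictor layer fails loudly by name.

MESS uses the standard piecewise similarity with `f` = percent of
reference values strictly below the probe value; the cell score is the
minimum over predictors, computed only for the predictors the model kept.
A zero-variance reference predictor scores 0 at its constant and is
penalized through a machine-epsilon range otherwise, with a warning.

The multi-GCM combination weights each GCM's projection by
`max(MESS, 0) + ε` (ε = 10⁻⁶) per cell and normalizes — a convex
combination, so the ensemble never leaves the envelope of its members,
novel-climate (negative-MESS) projections are suppressed, and the result
stays defined when every GCM extrapolates. The exact weighting function of
the published MESS-based ensemble index is not restated in the source
study; this clip-at-zero convex rule is this package's definition.

Reclassification to 1–10 uses equal intervals with the upper bin owning
each edge, `min(⌊10v⌋ + 1, 10)`, so class 10 is reachable at v = 1.

## Couple-and-weigh overlay

* **Elevation preference**: occurrence counts per 100-m elevation band,
  min–max rescaled to 1–10 with half-up rounding (GIS reclassification
  tools emit integers; half-up is this package's documented choice).
  Bands outside the occupied range score 1; if all occupied bands tie,
  they score 10.
* **River index**: reaches with Strahler order > 4 (the major rivers the
  species follows), raw score CSI − URB, min–max rescaled over retained
  reaches to 1–10; rasterization takes the maximum class per cell and
  riverless cells score 1 so the overlay is defined everywhere.
* **Forest polygons**: a point with reported area *A* ha becomes a disk of
  radius `√(A·10⁴/π)` m (local tangent-plane circle), optionally cut by a
  boolean forest mask; the mask can only remove area.
* **Weighted overlay**: the finer elevation/river layers are block-aggregated
  to the climate grid (mean for elevation, max for rivers so narrow
  corridors survive), then combined cell-wise with non-negative weights
  summing to 1 and rounded half-up into 1–10. The source study does not
  publish its layer weights; the default 0.5/0.25/0.25 privileges the
  climate signal, and `analysis/05_weighted_overlay.py` sweeps the climate
  weight to show the sensitivity rather than pretending a single truth.

## Circuit connectivity

Each valid cell is a node with conductance equal to its weighted
suitability class (no inversion — suitability is used directly as
permeability; a resistance transform `R = 11 − ws` is available for
sensitivity runs). Edges join 8-neighbours by default (4 by flag) with
conductance equal to the mean of the two cells, diagonals divided by √2
for the longer hop. These network conventions are the package's own
defaults, stated here because connectivity software rarely documents them.

* **Pairwise mode**: for every unordered focal pair, unit current enters
  one node and leaves the other; the potential difference is the effective
  resistance and per-cell current is half the sum of absolute incident
  edge currents. One factorization per graph component serves all pairs
  (ground an arbitrary reference node; inject +1/−1). Pairs split across
  components report infinite resistance and no current, with a warning.
  Cumulative maps *sum* per-pair currents.
* **Advanced mode**: cells inside destination polygons are tied to zero
  potential; one linear solve with the stated injections. Sources inside a
  ground are ignored with a warning; polygons too small to cover a cell
  center snap to the cell containing their centroid. Components with no
  ground carry zero current.
* **Solver**: dense Cholesky below 5,000 unknowns, otherwise conjugate
  gradient with Jacobi preconditioning at relative tolerance 10⁻¹⁰.
* **SCCI**: cell-wise `(F − C)/(F + C)` on current maps, defined 0 where
  both vanish; bounded in [−1, 1] and antisymmetric by construction.
* **Reachability**: a forest is reachable when its polygon lies within
  130 km (great-circle, densified boundary scan) of any occurrence.

## Niche overlap and gap analysis

Two point clouds overlap unless an SVM with a near-hard margin
(C = 10⁶, configurable) separates them perfectly on the training points —
the perfect-separability convention of SVM-based niche-overlap tests.
Predictors are z-scored on the pooled set, making verdicts invariant to
affine rescaling. The polynomial kernel is `(γ·x·x′ + 1)²` with
γ = 1/n_predictors. The libsvm iteration count is capped (2·10⁵) because a
hard margin on inseparable data can cycle; a capped, imperfect fit already
implies the correct "overlap" verdict. Groups sharing an identical point
are declared overlapping without fitting, and groups below 3 points are
left untested.

Gap analysis intersects occurrences with Natura 2000 and nationally
designated polygons ("both" when covered by both kinds, including polygons
carrying the joint designation), repairs invalid polygons by zero-width
buffer, and measures great-circle distance to the nearest forest polygon
boundary (0 inside).

## Synthetic landscapes

The generator emulates what the analysis assumes about real data:

* predictors are Gaussian-filtered white noise (σ = 5 cells) plus a
  latitudinal gradient, z-scored — spatially autocorrelated smooth fields;
* requested collinear pairs are imposed *exactly* by Gram–Schmidt on the
  valid cells, so a VIF screen has a real target;
* future surfaces add a per-GCM, per-predictor trend (scaled by decades
  since 2020 and an SSP multiplier of 1.0 / 1.5 for the moderate / high
  pathway) plus smooth noise — so GCMs disagree and MESS has something to
  flag; a zero trend with zero noise reproduces the current surface
  bit-for-bit;
* occurrences are drawn with probability proportional to
  `logistic(α + β·z)` of the z-scored predictors, jittered inside their
  cell with full-precision coordinates and years in [1990, 2020], so the
  default screening keeps them all (the filters are exercised separately
  with corrupted records);
* rivers are seeded random walks with Strahler orders cycling 1–8 (both
  sides of the order filter always exist), CSI/URB uniform in [0, 100];
  forest areas are log-uniform in [1, 10⁴] ha; protected rectangles cover
  all three designation kinds.

Everything is bit-reproducible under the seed. What the generator does
**not** emulate: real bioclimatic variable semantics and units, sampling
bias in occurrence data, realistic river topology (confluence-consistent
Strahler numbering), anisotropic terrain, or the spatial co-location of
forests with suitable climate. Passing tests therefore demonstrate the
*mechanics and identifiability* of the pipeline on data satisfying its
assumptions, not predictive skill on real landscapes.

## Problem sizes

The desk-scale study (`StudyConfig`) uses a 40° × 20° window at 0.5°
(3,200 cells, ~3,040 valid), 6 predictors with one collinear pair at
r = 0.95, 260 occurrences, up to 1,000 pseudo-absences (the 130–250 km
annulus on this window holds ~700 eligible cells, so the achieved count is
reported), a 2 × 2 tuning grid up to 250 trees with 5-fold CV, 12 focal
populations for the pairwise circuit, and all 6 future scenarios. These
sizes are the package's default study conditions; every operation accepts
larger inputs.

## Known limitations

* Geodesic buffers use the local tangent-plane approximation — adequate
  below a few kilometres, not for continental-scale buffers.
* The per-pair circuit solve is exact but scales with (pairs × solve); no
  hierarchical or preconditioned multigrid path for very large rasters.
* The SVM separability verdict is binary; it carries no significance test.
* Polygon areas in hectares use a cos(latitude) planar correction, not an
  ellipsoidal area formula.
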