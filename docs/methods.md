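# Methods

This note documents the models and procedures the package implements, the
default parameters and why they were chosen, what the synthetic-data
generator does and does not emulate, and the numerical conventions that
matter for reproducing results.

## The two-scenario design

The analysis contrasts two predictor sets over one study area: a *natural*
scenario (climate + terrain layers only) and a *disturbance* scenario that
additionally includes a categorical land-use layer. Both are fitted to the
same presence / pseudo-absence data; differences between their classified
habitat maps — total suitable area, spatial continuity, centroid position —
are attributed to the land-use signal, and the paired-map rubric plus
G-test asks whether that attribution is statistically defensible rather
than model noise.

## Data preparation

* **Spatial thinning.** Occurrences are thinned so no two retained points
  lie within a radius (default 30 km, great-circle) of each other. The
  algorithm is a greedy pass over a seeded random ordering: visit points in
  random order, keep a point iff it is far enough from everything already
  kept. Thinning is idempotent; the visiting order is the only stochastic
  element and is fixed by the seed.
* **Collinearity filter.** Continuous predictors are filtered greedily in a
  priority order: a variable is kept iff its absolute Pearson correlation
  with every already-kept variable is ≤ the threshold (default 0.8; the
  pairing experiment conventionally relaxes it to 0.9). The default
  priority is the canonical surviving-variable order of a bioclim+terrain
  analysis (hillshade, bio15, alt, bio08, bio12, bio17, aspect, bio07,
  slope, bio02) when all ten are present, otherwise descending variance.
  Categorical layers are never tested, only passed through.
* **Pseudo-absences.** Default 500, drawn uniformly without replacement
  from all valid cells that do not contain a presence, optionally excluding
  a buffer around presences (default 0 km: with only presence records there
  is no evidence the species is absent anywhere specific, so the whole
  study extent is background). Redrawn per repetition by default.
* **Splits.** Stratified by response class at the configured fractions
  (default 80/20). Exact integer counts can be forced per class to
  reproduce externally fixed splits (e.g. 45 training / 17 validation
  presences from 62 records, which plain rounding of 75:25 cannot yield).

## Learners and evaluation

The registry pins each algorithm id to a concrete, seeded implementation:
logistic regression (GLM), decision tree (CTA), random forest (RF),
gradient-boosted trees (GBM and XGBOOST), a single-hidden-layer perceptron
(ANN), a discriminant on a quadratic basis (FDA), and regularized logistic
regressions on hinge (MARS) and linear+quadratic+hinge (MAXENT) feature
bases. Continuous features are standardized and categorical features
one-hot encoded inside each pipeline. Hyperparameters are fixed in code so
that a (algorithm, table, seed) triple always reproduces the same fit.
Fits that raise or return non-finite probabilities are recorded as failed
and excluded downstream — they remain in the bookkeeping, since failure
counts are themselves a result.

Evaluation is on the held-out split only: rank-based AUC (midrank tie
handling) plus confusion-matrix metrics (sensitivity, specificity, TSS, κ,
CSI) at the TSS-optimal threshold. Threshold candidates are the midpoints
between consecutive sorted unique scores; ties break toward the smaller
threshold. The composite score γ applies conditional weights 0.5/0.3 at
per-metric thresholds (CSI 0.3, κ 0.4, AUC 0.9, TSS 0.7) and divides by 4;
it is monotone in every metric and bounded by 0.5.

Ensembles take the top-*k* (default 5) fits by the selection metric — ties
broken by higher AUC, then lower repetition index — and average member
probabilities pointwise. TSS-ranked selection applies a TSS ≥ 0.7
eligibility gate (the same bar γ uses); AUC-ranked selection applies no
TSS floor by default, since a high-AUC model with a mediocre TSS is still
a legitimate committee member under that ranking.

Permutation importance of a variable is 1 minus the Pearson correlation
between predictions on the original table and on a table with that column
permuted, averaged over permutations (default 5–10) and clipped to [0, 1].
Constant predictors have importance 0 by definition.

## Habitat grading and accounting

Classification uses exact Fisher–Jenks natural breaks: a dynamic program
over the sorted value sample minimizing total within-class sum of squared
deviations, with four classes (unsuitable, poorly, moderately, highly).
The exact program is O(k·n²); samples above 10,000 values are thinned to
every *k*-th sorted value to bound runtime (a 100×100 map is still exact).
Breaks are computed per map by default; a `breaks=` argument lets periods
share one set. Cell areas are treated as constant (cell size squared) with
no latitude correction; a weighted mean-center variant is available, but
the default centroid is the unweighted mean of suitable cell-center
coordinates over classes {poorly, moderately, highly}. Distances and
bearings are haversine on a sphere of radius 6371.0088 km — at the ≤ 50 km
scales where distances gate decisions (thinning, buffers) the difference
from projected Euclidean distance is negligible.

Percentage changes are always relative to the *first* report of the
comparison, so "scenario 2 vs scenario 1" divides by the scenario 1 total
and "2090s vs scenario 2" divides by the scenario 2 total; deltas are
signed (negative = loss).

## The pairing rubric

Each validation point is scored against the control (natural) and test
(disturbance) classified maps by five exclusive rules applied in order:
suitable in control only → control; suitable in test only → test; both
suitable at different grades → higher grade; equal grades but evident
fragmentation in the test map within the radius → test (flagged); else no
point. "Evident fragmentation" is not standardized anywhere, so it is
operationalized as: within the buffer (cells whose centers lie within
50 km of the point), the test map splits suitable cells into more
8-connected patches than the control *and* its suitable-cell fraction is
lower by at least a margin (default 0.10). The two-condition form rewards
break-up while excluding uniform shrinkage, and both parameters live in
`RubricConfig`. The fragmentation column in tally tables is bookkeeping
recorded alongside the group tallies, not bounded per repetition.

The G-test on the repetitions × (control, test) count table is the
likelihood-ratio statistic G = 2·ΣO·ln(O/E) with independence-model
expectations, 0·ln 0 ≡ 0, no continuity or Williams correction, and
df = (r−1)(c−1); equality and fragmentation columns do not enter the
table. Random pairing draws uniformly among the top-20 models by γ.

## The synthetic study area

The generator produces the conditions the analysis assumes rather than a
physical climate:

* **Continuous layers** are Gaussian-smoothed white noise (declared
  smoothing radius in cells, default ~6), standardized. Pairwise
  correlation targets are met *exactly* by empirically orthogonalizing the
  partner field before mixing; the default 19 climate analogs include
  eight pairs correlated above 0.8, mimicking the redundancy of a bioclim
  set (temperature family, precipitation family).
* **Terrain** comes from a synthetic DEM (km): Horn 8-neighbor slope,
  downslope aspect in [0°, 360°) with flat cells flagged −1, and hillshade
  in [0, 1] for a sun at azimuth 315°, altitude 45°. Border cells use
  one-sided differences via linear edge extrapolation.
* **Land use** (6 classes: woodland 45%, shrub 10%, grassland 10%,
  cropland 20%, urban 10%, water 5%) is assigned in two stages: an
  *independent* fine-scale footprint field places cropland and urban cells
  anywhere — deliberately including climatically suitable cells, because a
  human footprint that only occupied bad habitat could neither remove nor
  fragment anything — while the remaining natural cells are banded along a
  precipitation-anchored ordering so woodland occupies wet cells. This
  yields the woodland-dominated occurrence profile (roughly 90%+ of
  presences in woodland against a 45% areal share) that motivates treating
  land use as a disturbance axis.
* **The virtual species** has a known logistic niche over per-layer
  z-scores — intercept −12, +9·z(bio12), +4.5·z(slope), −1.5·z(bio12)² —
  forced to zero on cropland/urban cells. The steep response makes it a
  habitat specialist occupying under a tenth of the study area; that is
  what gives single models the strong discrimination (AUC ≈ 0.9+) a
  two-scenario comparison presupposes, and it makes precipitation and
  slope the recoverable top-2 drivers. Presences are drawn without
  replacement proportional to true suitability and reported as cell
  centers.
* **Scale.** The reference landscape is 100×100 cells of 10 km — a
  1000-km domain standing in for a subcontinental study region at reduced
  scale. At that size 30-km thinning retains roughly 45–50 of 82 raw
  presences (the same order as a 62-of-82 retention on the real extent),
  and the 50-km fragmentation buffer spans ~4–5 cells, enough for patch
  analysis. Pipeline smoke tests use 40×40–60×60 grids with 2 repetitions
  and a reduced learner set; the seeded recovery study uses 10 landscapes
  at the full 100×100 with three learners per scenario.

What the generator does **not** emulate: physical climate fields and their
cross-variable constraints, anisotropic terrain, realistic land-use
geometry (road networks, river valleys), observation bias in occurrence
records, and spatial sampling autocorrelation beyond what smoothing
induces. Passing recovery tests therefore show the *pipeline* is sound —
signal in, signal out — not that any particular real-world prediction is
right.

## Future periods

Future climate layers are represented as additive per-variable deltas on
the current stack (configured per period), standing in for downscaled
scenario rasters. A user can instead point the pipeline at a directory of
real ASCII-grid layers; the synthetic path exists so every stage is
testable without external data.

## Reproducibility conventions

One master seed drives a run; per-stage seeds are derived via CRC-hashed
stage keys through a seed sequence (all below 2³¹), recorded in the run
manifest before use. Every generator and sampler is a pure function of its
arguments including the seed; reruns of the same config are byte-identical
down to the CSV reports.

## Known limitations

* Learner "defaults" are this package's pinned choices, not a reproduction
  of any other platform's internals; absolute metric values on real data
  will differ from other toolchains even on identical inputs.
* The exact Jenks program subsamples above 10,000 values; break values on
  very large rasters are therefore approximate (bounded by sample density).
* Cell areas ignore the cos(latitude) convergence of meridians; at
  subcontinental extents this biases northern/southern area totals by a
  few percent relative to spherical cell areas.
* The fragmentation criterion depends on the buffer radius, margin and
  connectivity chosen; conclusions about fragmentation should be checked
  for robustness across those settings.
* Pseudo-absence uniformity ignores sampling bias; environmental-distance
  or target-group strategies are out of scope.
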