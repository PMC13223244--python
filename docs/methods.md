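# Methods

This note records the modeling choices behind `urban330`: how each rule
is operationalized on 100 m rasters, what the synthetic cities emulate
(and what they do not), and the numerical conventions that make results
reproducible.

## Data model and conventions

All layers live on axis-aligned, north-up grids in a projected
meter-based coordinate system; cell (row, col) covers the half-open
square with row 0 at the top, and a cell's location is its center. The
analysis layers (building height in m, tree count, tree-cover density in
%, population) share one 100 m grid; land use is categorical at 50 m on
the same origin; income sits on its own coarser grid (200 m default,
1 km supported). Only nested grids (integer cell-size ratios, shared
origin) are resampled — there is no general reprojection, because every
distance in the method (100/250/300/500/1000 m) is a Euclidean distance
in meters.

Rasters are stored as single-band ESRI ASCII grids: a plain-text format
that round-trips values, mask and geotransform exactly (floats are
written with `repr`, which is lossless for float64). ASCII grids carry no
CRS tag, so degree-scale grids are rejected by a cell-size heuristic
(cells smaller than 0.5 "meters" are taken to be geographic). Vector
data (boundaries, green polygons, buffers) are GeoJSON.

Nodata propagates: a cell is excluded from any cross-layer result if any
input is nodata there, and such cells carry no population weight. The
score-share denominator is the population mass on valid cells, which
keeps the four score shares summing to one on masked inputs and equals
the boundary population on complete bundles.

## Rule 3 — tree visibility by viewshed

Observation points are placed by dart throwing: uniform candidates in
the boundary's bounding box, accepted when inside the boundary and at
least `min_spacing_d_m` (default 100 m) from every accepted point;
sampling stops after `max_sample_attempts` (default 2000) consecutive
rejections. This satisfies the minimum-spacing property exactly, is
seedable, and at the stopping point is near-saturated, so with
`radius_r_m` ≥ the spacing essentially every cell center lies within
range of some viewpoint. Viewpoints are continuous coordinates anywhere
in the boundary, not snapped to cells or buildings: population enters
the metric only through the final share.

Terrain is flat; the obstacle layer is building height (an optional DEM
could be added to both endpoints and obstacles, but none is wired in by
default). Observer and target sit at 1.6 m. The line-of-sight predicate
is computed *exactly*: the sight segment is cut at every grid-line
crossing, each traversed cell contributes its exact parameter interval
(edge and corner touches of zero length are dropped at 1e-12 in the
segment parameter), and the cell blocks when its height reaches the
sight line anywhere on the interval — since the line is linear in the
parameter, that is a single comparison against the interval minimum.
Ties block (an obstacle exactly at the sight line is opaque):
conservative and deterministic. Fixed-step sampling along the ray was
rejected because it can miss cells clipped near corners; the exact
traversal is what lets the test suite demand cell-for-cell equality with
an independent slab-clipping oracle. The observer's and target's own
cells are excluded from the test, so a co-located 100 m building cannot
occlude trees in the same cell — at this grain, proximity implies
visibility unless an *intervening* cell blocks.

Exposure is the per-cell count of viewpoints that see the cell (additive
over points; cells outside every radius disk stay 0). Compliance needs
exposure ≥ 1 *and* tree count ≥ 3; the count is kept for diagnostics
only. The visibility target is the tree-bearing cell itself.

## Rule 30 — neighborhood canopy

Blocks are anchored at the raster origin (the anchor is unspecified in
general; anchoring to the origin makes results reproducible and is
recorded here). Every 100 m cell belongs to the block containing its
center, which keeps block sizes that are not whole cell multiples (250 m
on a 100 m grid) well defined. A block's canopy is the arithmetic mean
of tree-cover density over its non-nodata cells with centers inside the
boundary — the natural area-fraction reading when density is an area
percentage — and edge blocks are evaluated on their inside cells rather
than dropped, so boundary population is not asymmetrically removed.
Compliance is mean ≥ threshold (inclusive, default 30%), broadcast back
to the member cells. At block size 100 m the aggregation is the
identity, giving the per-cell threshold as a degenerate case.

## Rule 300 — green-space proximity

Green areas come from the land-use raster: cells inside the urban area
(class code below the urban ceiling, default 2000) with a green class
code, polygonized by 4-connectivity (corner contact does not merge
patches) and filtered to area ≥ 1 ha, inclusive. A patch intersecting
the city boundary is kept and buffered whole even if it extends outside.
Buffers are Euclidean with 16 arc segments per quadrant; for a convex
square park the buffered area then matches the Minkowski closed form
A + P·r + πr² to well under 0.5%. A cell complies when its center lies
in the closed buffer union (center-in-buffer matches the
population-at-center semantics used throughout; the closed boundary
affects only a measure-zero set of centers). The generalized
`population_within_distance` uses the same buffer-and-test path, so at
300 m it reproduces the Rule-300 share *exactly*, not approximately.
Network (walking) distances are out of scope by design.

## Joint score and sensitivity

The three compliant sets are computed independently and intersected at
the 100 m cell level; the score is their cellwise sum. Every assessment
records a configuration fingerprint (d, r, block size, thresholds,
buffer, seed), and the sensitivity sweep evaluates the Cartesian product
of (d, r, block size) with the viewshed reused across block sizes —
row results are identical to independent runs, which the tests assert.
Multi-city pooling is a population-weighted mean of score shares.

## Synthetic cities

`generate_city` emulates the statistical structure of the real inputs:
spatially autocorrelated building heights (log-normal, mean 12 m, SD 6 m
on a ~35% built mask), canopy as a smoothed Gaussian field mapped to
[0, 100]% (mean 25%, SD 15%, correlation range 800 m), Poisson tree
counts with intensity proportional to canopy (mean 2 trees/cell),
population (default 100,000 on a 6 × 6 km grid, i.e. a mid-size European
core) allocated multinomially over built cells weighted by building
height, rectangular parks burned into a 50 m land-use raster with
LUISA-like class codes, and an income grid rank-coupled to local
greenness. The coupling is a Gaussian copula on the ranks of a composite
greenness index — standardized mean canopy minus standardized distance
to the nearest green land-use cell, per income cell — at the Pearson
coefficient 2·sin(πρ/6) matching the target Spearman ρ. Park proximity
is part of the index deliberately: with canopy-only coupling, cells near
parks (which earn the Rule-300 point regardless of wealth) dilute the
income signal of the top compliance category, whereas in real cities
park access and vegetated surroundings co-vary. All draws flow from one
seeded generator per city; generation is bit-reproducible.

What the generator does *not* emulate: street networks, terrain, blue
space, irregular boundaries, temporally evolving cities, or the empirical
marginal distributions of any specific city. Passing tests therefore
demonstrate the correctness and calibration of the *pipeline* under
known structure, not the real-world magnitudes of the three metrics.

`generate_city_with_planted_compliance` is the recovery oracle: a flat,
uniformly populated city where the Rule-3 set is an exact count of
tree-bearing cells (everything is visible with no obstacles and a dense
point set), the Rule-30 set is whole 1 km blocks at 40% vs 10% canopy,
and the Rule-300 set is a full-height park strip whose 300 m buffer
reaches exactly three further 100 m cell centers. The returned expected
assessment is computed from the constructed masks (achieved fractions —
block and column granularity quantizes raw targets), so the pipeline
must recover it to within discretization (±0.02, dominated by the few
cell centers a near-saturated point set can leave uncovered).

## Equity analysis

The Green Space Category is the mean score of the 100 m cells nested in
each income cell (omitted when uncovered). Box summaries of income per
category round the mean half-up to 0..3 (the continuous mean is kept);
income is displayed on log10. Rank correlations are Spearman's ρ with a
two-sided permutation p-value (9,999 seeded permutations by default) —
exact at small n, no asymptotic claims; constant inputs raise rather
than returning an undefined ρ. Income cells are weighted uniformly, not
by population. The bivariate classification assigns each city a quartile
(linear-interpolation breaks; ties to the lower quartile) of each of two
covariates, giving 16 classes that always partition the city set; the
direction of an aridity-type index is taken from the input's own
convention and never hard-coded.

## Problem sizes and tolerances

The shipped tests and the acceptance script run on 20×20–60×60 cities
(4–36 km²), 10–50 seeds per property, d ∈ {100, 250, 500} m and
r ∈ {100, 250} m — sizes chosen so the full suite completes in well
under a minute per property while leaving the statistical margins
comfortable (planted recovery errors observed at 0 against a ±0.02
bound; copula recovery within ±0.09 against ±0.1). The Rule-30
grid-robustness spread between 1 km and 100 m neighborhoods is typically
0.03–0.11 on smooth canopy fields (correlation range 1 km) and is
sensitive to where the canopy field sits relative to the 30% threshold;
it is reported, not assumed.

## Known limitations

- Visibility at 100 m grain cannot resolve window views, narrow sight
  gaps between buildings, or sub-cell tree placement.
- Flat-terrain viewsheds: sloped terrain would need a DEM added to the
  obstacle layer and both endpoints.
- Euclidean proximity ignores barriers (rivers, rail, fenced land).
- Green-space *quality* and blue spaces are not scored.
- The ESRI ASCII format carries no CRS; callers must ensure all inputs
  share one projected system.
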