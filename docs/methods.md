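# Methods

This note documents the models implemented in `parkzoning`, the defaults
chosen where the method leaves a choice open, and what the synthetic data
do and do not establish.

## Assessment grid

The park footprint (cells whose zone mask is core or general) is tiled
with square assessment units anchored at the raster origin, 400 m by
default — the common rule of thumb that landscape sample areas should be
a few times the mean patch size. Units are identified by `(row_block,
col_block)` with 0-based, north-up, half-open cell intervals, so unit ids
and bounds are reproducible. Boundary units are retained with their
reduced in-park area `A_k` (never padded or discarded), which makes area
accounting exact: the sum of all `A_ki` equals the in-park non-nodata
cell count times the cell area. Units with `A_k` below 25% of a full unit
(configurable) are flagged: they still receive surface values and zone
labels, but their own field values do not enter the kriging sample set,
because metrics on slivers are unstable.

Nodata cells count toward `A_k` (they are inside the park) but toward no
class, so `Σ_i A_ki ≤ A_k` with equality on nodata-free units.

## Landscape metrics and the risk index

Per class *i* within one analysis region (the core area by default):
`C_i = n_i/A_i`, `N_i = (A/2A_i)·sqrt(n_i/A)`, `D_i = (M_i+L_i)/2`,
`S_i = 0.6·C_i + 0.3·N_i + 0.1·D_i`. Notes on choices:

- **Isolation form.** `N_i` is implemented in the standard
  isolation-index form `(A/2A_i)·sqrt(n_i/A)`; the formula lives in one
  place (`metrics.class_metrics`) so an alternate reading can be swapped.
- **Connectivity.** Patch labeling uses 8-connectivity by default (the
  FRAGSTATS convention), configurable to 4. Nodata and out-of-region
  cells break connectivity — the conservative reading.
- **Scope.** Metrics are "landscape-global" by default: `n_i, A_i, M_i,
  L_i, A` are computed once over the whole region, so `R_i` is one
  number per class and per-unit ERI variation comes entirely from
  composition `A_ki/A_k`. A per-unit scope (recomputing metrics inside
  each unit window) is available via `metrics.scope`.
- **No min–max normalization** of `C/N/D` before weighting: the weighted
  sum is applied to the raw indices. Units: areas in km², so `C_i` is in
  patches/km².

The loss index is `R_i = F̂_i·S_i` with vulnerability ranks `F_i` fixed by
the legend (1 building land … 12 bare land). `F̂_i = F_i/ΣF_j` (= `F_i/78`
for the 12-class legend) by default so ERI magnitudes land near a 0–1
scale; raw ranks are available (`eri.normalize_F: false`). The choice is
a uniform rescaling of every `R_i` and hence of every `ERI_k`; Jenks
breaks rescale with the data, so grade memberships and the four-zone map
are invariant to it.

`ERI_k = Σ_i (A_ki/A_k)·R_i` is a convex combination of the unit's class
loss indices — tested as an invariant.

## Ecosystem service value

The 12 mapped classes collapse to 8 valuation groups. The mapping the
method leaves open is configurable and defaults to: the four forest
classes → "forest land"; **garden plot → forest land** (woody cover; a
switch maps it to cropland instead); **building land → zero equivalents**
(standard equivalent-factor practice). The shipped equivalence table
follows the national per-unit-area equivalent literature (11
subcategories in 4 categories; forest-row sum ≈ 23 equivalents) and is a
placeholder for a park-specific table supplied as a YAML catalog; one
equivalent is worth 231 427 yuan/km² by default (a config scalar — the
underlying grain-price statistics are not part of this package).

Money is carried internally in 万元 (RMB 10⁴) per km²; the report layer
converts totals to RMB million (万元/100) and rounds half-even to 2
decimals — rounding happens only there. Category columns partition the
total coefficient, so per-unit category values partition `ESV_k` exactly;
report totals use compensated summation (`math.fsum`) and are therefore
independent of unit ordering to well below 1e-9.

## Kriging

Unit-centroid values are interpolated per zone (ERI over core, ESV over
general; the two fields are never blended across the zone boundary).
Defaults: method-of-moments semivariogram with 12 lags to half the
sample-cloud diameter; spherical model (exponential and gaussian
available, practical-range convention) fitted by weighted least squares
with pair-count weights, bounded parameters, and a fixed ladder of range
starts — the fit is deterministic and falls back to a pure-nugget model
with a warning when degenerate. Ordinary kriging uses the 16 nearest
samples per target; the unbiasedness constraint makes weights sum to 1
(checked to 1e-10). A singular system retries with all samples, then
falls back to inverse-distance weighting with a warning (this is also
the graceful path for a constant field, whose variogram is identically
zero). Predictions are exact at sample locations when the nugget is
zero.

Surfaces are produced at the assessment-unit resolution (one cell per
unit): grading and zoning then operate per surface cell, and area
accounting can use each unit's true `A_k`, keeping the zone partition
exact. The source workflow kriged to a display raster inside a GIS; its
settings are unknown, so numeric surface agreement is not a goal — every
choice here is an explicit config value.

## Grading and the four-zone map

Grades come from exact Fisher–Jenks dynamic programming (minimum
within-class sum of squares), `k = 5` by default. Boundary semantics:
grade intervals are half-open with break values belonging to the upper
grade (`grade II = [b₁, b₂)`), and each reported break equals the
smallest value of its upper class. For more than 4000 values the DP
(O(kn²)) runs on an even-stride subsample of the sorted values of size
4000; grading of the full data always uses all values. The DP is verified
against an exhaustive-partition oracle for small n.

The four-zone map cuts the core at the first ERI break (CHR = ERI
grades II–V) and the general area at the second ESV break (GHE = ESV
grades III–V). Cuts are data-driven by design — the published thresholds
were themselves that study's natural breaks, and it is the rule, not the
numbers, that transfers to new rasters — but fixed numeric cuts can be
given in config. Zone and grade areas are sums of unit `A_k`, so the four
zones partition the park area exactly and percentages sum to 100.

## Synthetic data

The generator emulates the structure the analysis assumes, not any real
geography: a forest-dominated mosaic (62% arbor forest by default over
the 12-class legend), produced by modified random clusters — Bernoulli(p)
site percolation, 4-connected clustering, cluster-to-class assignment by
target proportions, nearest-cluster fill. `p = 0` degenerates to an
independent multinomial raster. Realized class proportions track the
targets within ±3 percentage points on rasters ≥ 200×200.

The clumping parameter controls patch size through cluster coalescence,
which is the dominant effect for `p ≳ 0.3`; below that, sparse markers
produce large Voronoi-like fill regions and mean patch size *rises* again
as `p → 0`. The default `p = 0.45` sits inside the monotone regime, and
the monotonicity property is asserted there (`p ∈ {0.3, 0.45, 0.55}`).

The park footprint is a mildly perturbed ellipse; the core is the
distance-to-boundary superlevel set hitting the requested share of park
cells (51.82% by default, matched within ±1%), which guarantees a
contiguous core fully surrounded by the general area. Fragmentation
hot-spots (irrigated field / garden / bare patches at 45% fill) are
scattered around the core–general border, and near-solid water/wetland
pockets inside the general area — the configurations that should, and in
tests do, produce locally elevated ERI and ESV.

The default scene is 260×260 cells at 100 m (≈ 580 km² park before the
footprint is carved, ≈ 2 400 assessment units at 400 m) — the same
spatial scale as a mid-sized national park, small enough that the full
pipeline runs in about a second. What passing tests on synthetic scenes
establish is the correctness and invariances of the computations
(conservation, convexity, oracle equivalence, determinism), not that any
particular real park has a given risk or value distribution: the
generator has no terrain, climate, seasonality, or classification error,
and its class geometry is statistically stationary in a way real parks
are not.

## Numerical conventions

- Areas from integer cell counts × cell area; conservation asserted
  exactly.
- Grade/zone boundary values always belong to the upper class.
- All randomness flows through `numpy.random.default_rng(seed)`; the
  pipeline seed is part of the config, and reruns with the same config
  are byte-identical in their CSV outputs.
- Degenerate inputs: empty regions, zero-area units, all-equal values,
  coincident kriging samples and zero totals raise informative errors or
  flagged reports rather than NaNs.

## Known limitations

- ESRI ASCII grid is the only raster format (text, lossless round-trip);
  there is no reprojection — raster and mask must share one grid.
- Per-unit metric scope is O(units × labeling) and noticeably slower
  than the default landscape-global scope.
- The equivalence table shipped as default is a national-style generic
  table; park-specific valuation requires supplying the real table.
- Kriging assumes isotropy and a single variogram per zone.
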