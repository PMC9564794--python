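# Methods

## Scope and data model

The pipeline operates on a single co-registered raster grid (default
30 m × 30 m cells, pixel area A = 900 m²; projected metres, row 0 north,
0-based indices) plus a three-level nested polygon hierarchy
(county ⊃ township ⊃ village). All continuous layers are float64; LULC
class, hydrologic soil group and zone ids are int32. The nodata sentinel
(−9999) never enters arithmetic: operations mask it or propagate it, as
stated on each function. Polygons are rasterized by pixel-center
containment; a center lying exactly on a shared edge goes to the zone with
the smaller id, which makes rasterization deterministic. Reprojection and
resampling are out of scope — inputs must arrive pre-aligned.

GeoTIFF I/O writes the grid geometry into the standard geo tags
(ModelPixelScale, ModelTiepoint), the nodata value into GDAL_NODATA, and
units/CRS label into the image description, so rasters round-trip losslessly
and are readable by standard GIS tooling.

## Service models: assumptions and defaults

**Crop production (CP).** The regional production total GPs (default
2.09 × 10⁶ t) is distributed over cultivated pixels proportionally to the
Vegetation Condition Index, the min-max of NDVI computed over cultivated
pixels only. Allocation conserves GPs to 10⁻⁹ relative. Demand is
population × per-capita consumption Ca (default 0.1221 t/person/yr).

**Water retention (WR).** Supply is Budyko-curve water yield minus surface
runoff. For vegetated classes the evaporative index is
AET/P = (1 + wR)/(1 + wR + 1/R) with dryness index R = Kc·ET₀/P. The
seasonality parameter w is not physically observable; we use the standard
parameterization w = Z·AWC/P + 1.25 with Z configurable (default 5), and a
direct w raster can be substituted. For non-vegetated classes the curve is
undefined and we take AET = min(Kc·ET₀, P), the accepted convention for
this model family (the per-class coefficient table flags these classes
explicitly). Runoff is P·C with per-class runoff coefficients; water (C = 0)
retains its full yield, built-up and unused land (C = 1) shed all rain, so
built-up retention Y − P is typically *negative*. Negative retention
propagates by default (a config switch clamps at 0). Demand sums four
components: domestic (per-capita Wc × population, every pixel) and
agricultural/industrial/ecological subdistrict totals spread uniformly over
that subdistrict's cultivated, built-up, and forest+grassland pixels
respectively; the 6-class LULC has no separate industrial class, so
industrial use falls on built-up pixels (an industrial mask can restrict
this). A subdistrict reporting consumption with no pixels of the using class
is an error naming the zone. Allocation conserves the table totals exactly.

**PM2.5 reduction (PR).** Supply is dry deposition on forest: flux
F = V_d·C_h·3600/10⁶ g/(m²·h) (deposition velocity V_d = 0.0009 m/s), leaf
area TCLA = A·LAI, daily removal F·TCLA·24·(1 − R) with resuspension
R = 0.03, annualized over D non-rainy days (default 245, a scalar because no
daily weather pathway exists). The hourly concentration C_h is taken equal
to the annual-mean raster — only annual concentrations are available at
this data tier. Demand is the pollutant load above the WHO annual guideline
(10 μg/m³) in the boundary-layer column (H = 200 m): (Cₐ − 10)·H·A·365·24 μg
where Cₐ exceeds the guideline, else 0. The supply model yields grams, the
demand formula micrograms; budget aggregation converts demand to grams so
the two sides of the PR budget are commensurable.

**Flood mitigation (FM).** SCS curve-number retention for a design storm P
(unstated upstream; configurable, default 100 mm): I = 25400/CN − 254,
runoff (P − 0.2I)²/(P + 0.8I) when P > 0.2I else 0, FM = 1 − runoff/P.
CN = 100 converts all rain to runoff (FM = 0); CN = 0 (open water) is
treated as the infinite-retention limit, FM = 1, since the runoff expression
is singular there. Demand combines population vulnerability
(⅓ total + ⅓ elderly + ⅓ child density, min-max normalized) and economic
vulnerability (impervious-density classes: > 80 % → 8, 50–80 % → 7,
20–50 % → 6; built-up below 20 % → 5; unused 4, cultivated 3, grassland 2,
forest/water 1; min-max normalized), weighted ½/½ and min-max normalized
again. All min-max normalizations use the non-nodata pixels of the full
grid — one consistent reference frame — and a constant field degenerates to
all-zero with a warning rather than dividing by zero.

**Heat mitigation (HM).** Cooling capacity CC = 0.6·shade + 0.2·ETI +
0.2·albedo with ETI = clip(Kc·ET₀/ETmax, 0, 1). The park effect CCpark is
the distance-decay-weighted mean of CC over green pixels within the cooling
distance (default 450 m), with kernel weights e^(−d/d_cool) normalized to
sum to one. The normalization is deliberate: an unnormalized sum over a
green indicator is unbounded and cannot be compared against CC ∈ [0, 1].
A pixel keeps its own CC when it belongs to a green patch of at least
20 000 m² (4-connected components) or when CC ≥ CCpark; otherwise it takes
CCpark; with no green within reach it keeps CC. Demand is urban-heat-island
intensity against the cropland-mean land surface temperature. The default
("intended") mode scores pixels *hotter* than cropland, max(0, Tᵢ − T̄c);
a "printed" mode retaining the opposite inequality convention of the
source formula is kept for fidelity. Either raw field is min-max normalized.

**Landscape recreation (LR).** Supply is the forest+grassland area share of
the (village) zone, broadcast to its pixels; demand is population density
(person/m²) × the planning guideline of 13 m²/person. Demand may exceed
1 m²/m² where residents outnumber what a pixel can host.

## Budgets, bundles, drivers

Supply and demand aggregate to zones by **sum** for extensive services
(CP t, WR m³, PR g) and by **mean** for dimensionless indices (FM, HM, LR);
the method is recorded per table. ESDR = (S − D)/((Smax + Dmax)/2) with
maxima over the zones of each scale, so budgets are scale-dependent by
construction; ESDR is invariant to a common positive rescaling of all S and
D and bounded in [−2, 2]. Where negative WR sums occur, the raw sums stay in
the S column (preserving hierarchy additivity) and the ESDR input is floored
at zero — a zone that retains nothing supplies zero, not negative, water.
Map classification uses |ESDR| ≤ 0.1 as "balance" by default (configurable);
the normalization used before clustering follows the min-max formula to
[0, 1], with an optional rescale to [−1, 1].

Bundling runs k-means (Lloyd, Euclidean, best of 25 restarts, seeded) on the
column-normalized ESDR matrix of each scale independently; k defaults to 6
and is never silently overridden, but the within-cluster-sum-of-squares
curve over candidate k and its elbow (maximum perpendicular distance to the
chord) are always emitted. Bundles are renumbered 1..k by descending area
share so numbering is reproducible. Z-score profiles standardize the
per-service bundle means across bundles (population SD): Z > 0 marks a
service above the bundle-mean average. If a scale has fewer distinct zones
than k (e.g. 4 counties), the pipeline clamps k to the distinct-row count
and logs it.

The factor detector computes q = 1 − ΣN_hσ_h²/(Nσ²) with population
variances throughout (the printed form of the statistic only cancels with
the biased estimator). Continuous drivers are discretized into L = 5
quantile strata by default; quantile edges use the "lower" rule so the
stratification is invariant under monotone transforms of the driver, ties
resolve to the lower stratum, and duplicate edges merge with a warning.
Bundle labels are categorical while q needs numeric y; the default
"label-code" mode uses the integer labels (the field's common practice) and
an "indicator-mean" mode averages q over per-bundle 0/1 memberships (the
statistically cleaner reading); outputs are tagged with the mode.
Significance is a permutation test (default 999 permutations,
p = (1 + #{q* ≥ q})/(1 + n_perm)), assumption-free and exactly reproducible
under a seed, with significance declared at p < 0.1.

## The synthetic landscape

The generator emulates a rapidly urbanizing delta region: a patchy 6-class
LULC mosaic (default shares: cultivated 31.32 %, built-up 23.1 %, water
22.56 %, forest 12 %, grassland 6 %, unused 5 %), three urban cores with
exponentially decaying population, land surface temperature positively
coupled to impervious surface, a monotone NW→SE air-pollution gradient,
smooth climate/soil fields (precipitation mean 1093 mm), HSG classes A–D,
and per-village water-consumption tables whose totals are proportional to
the area of the using class (so the allocation precondition always holds).
LULC is allocated by ranking per-class smooth propensity fields (built-up
biased toward the cores, cultivated away from them), so realized class
shares match the configured weights to rounding while staying spatially
autocorrelated. The admin hierarchy is built by recursive rectangular
splitting with jittered cuts, which guarantees exact nesting.

The grid is a **scaled-down map of the whole region**: regional *totals* are
emulated rather than per-m² densities (population rescales to 25.49 million,
crop production to 2.09 × 10⁶ t), which preserves the region's overall
supply/demand balance — and hence the urban-core crop/flood/recreation
deficits — on a desk-sized grid. Elderly and child densities are fixed
fractions of population (0.18/0.12) with noise. Everything is driven by one
seeded generator, so a fixed seed reproduces the stack bit for bit.

What the generator does *not* emulate: real geography (lake shapes,
coastlines), census microdata, daily weather, the spatial covariance
structure of real remote-sensing products, or measurement error. Passing
recovery tests therefore demonstrates that the pipeline's inference is
correct when its model assumptions hold — not that those assumptions hold
for any particular real landscape.

### Planting bundles and drivers

For recovery tests, `plant_bundles` assigns each village an archetype label
(k × 6 profiles in [−1, 1]) linked to a chosen driver layer: labels follow
the driver's zonal-mean rank groups with probability 1 − e^(−effect), so
effect 0 decouples them entirely. It then (1) balances zone composition —
LULC re-drawn inside each zone at the global class weights along level sets
of a smooth field, population redistributed — so landscape composition stops
dominating between-zone budget variance, and (2) applies per-service levers
with strength `separation`: NDVI level (CP), the zone's water-table totals
(WR), forest LAI (PR), hydrologic soil group and vulnerable-group densities
(FM), land surface temperature (HM), and the zone population total (LR).
Sum-aggregated levers are zone-size-compensated so the planted signal is
independent of zone area. The population lever deliberately bleeds into
CP/WR/FM demand, as urban structure does in real landscapes; archetype
recovery is therefore tested on the full nonlinear pipeline, not on an
idealized linear response. Because ESDR emerges from six nonlinear models
plus per-scale maxima, planted zone vectors cluster *around* the archetypes
with separation-controlled tightness rather than hitting them exactly;
recovery is measured by adjusted Rand index against the recorded true
labels. When checking that the planted driver attains the maximum q, the
stratum count is matched to the planted group count (L = k), since quantile
rank bins then align with the rank-group construction.

## Numerical choices

* Conservation tolerances: crop total and water-table totals to 10⁻⁹
  relative; formula-oracle agreement to 10⁻¹² relative.
* The q-statistic centers y before the variance decomposition to avoid
  catastrophic cancellation under large offsets; q is clipped to [0, 1]
  against rounding at the boundaries.
* Degenerate inputs: constant fields in any min-max step normalize to zero
  with a warning; constant NDVI over the cultivated mask, an empty
  cultivated mask, zero ΣVCI, zero total variance in y, and k exceeding the
  number of distinct zone rows are errors.
* Park-effect convolution uses FFT convolution with a truncated kernel
  (radius d_cool); green patches use 4-connectivity.
* The run-level seed is forked via `SeedSequence` into independent
  generation/planting/clustering/permutation seeds (all < 2³¹), making every
  stage a pure function of (inputs, config, seed).
* Default problem sizes: 200 × 200 grid with 4/16/64 zones for full-pipeline
  runs and recovery studies; 500 replicates with 199 permutations for the
  null calibration of the permutation test (the nominal 0.1 level lies
  exactly on the 199-permutation lattice). A full default run completes in
  seconds on one CPU.

## Known limitations

* ES flows between zones are not modelled; budgets are strictly local.
* The InVEST-style supply models estimate *potential* supply; no
  actual-vs-potential distinction is made.
* Spatial-clustering statistics of budget maps (beyond visual pattern) are
  out of scope, as is any reprojection machinery.
* The 6-class LULC cannot separate industrial from residential built-up
  land; industrial water demand falls on all built-up pixels unless an
  industrial mask is supplied.
* County-scale inference runs on very few units (4 by default); q values at
  that scale are reported but carry little significance, mirroring the
  sparse-unit caveat inherent to coarse administrative scales.
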