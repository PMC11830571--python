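# Methods

This note documents the models and procedures implemented in
`structura`, the assumptions behind them, and the choices made where
the design was genuinely open.

## Rasters and grain aggregation

The package starts from paired digital terrain models (DTM) and digital
surface models (DSM) as single-band GeoTIFF rasters with square cells
(NEON's gridded LiDAR products are ~0.5–1 m). The canopy height model
is CHM = DSM − DTM, clamped at 0: negative differences are sensor
noise, and a canopy height model is non-negative by definition.
Heights below `min_height` (default **0.5 m**) are set to 0 and counted
as ground/gap. The threshold is configurable because the underlying
products are ambiguous about whether sub-0.5 m returns represent
understory vegetation or ground; treating them as gap keeps the
deep-gap fraction's "no return" semantics consistent.

Metrics are computed across a sweep of **grains** (linear pixel edge in
meters; default sweep 1, 5, 10, 15, 20, 25, 30, 40, 50, 60, 70,
100 m). Aggregation partitions the fine grid into grain × grain blocks
and records **both** the per-block maximum and mean: the per-pixel
maximum is the canopy top (or ridge elevation) within the pixel and
feeds the height/rugosity metrics, while the mean is the natural
smoother for the terrain window metrics. Partial edge blocks are kept
when at least 50% of their cells are valid — dropping them would bias
the pixel count downward on non-square sites. GeoTIFF I/O is built on
`tifffile` with the standard georeferencing tags (pixel scale,
tiepoint) and the GDAL nodata convention.

## Canopy metrics

All nine canopy metrics consume the aggregated CHM at one grain (at
grain = cell size the aggregation is the identity):

- **q95** — 95th-percentile of per-pixel max heights (linear
  interpolation between order statistics; the common default, fixed
  for reproducibility). Used instead of the maximum to suppress
  outlier returns.
- **MOCH** — mean of per-pixel max heights.
- **CR (canopy rugosity)** — *population* standard deviation of
  per-pixel max heights, in meters. The squared (variance) form is
  available via `variance=True`; the standard deviation is the default
  because rugosity is conventionally reported in height units.
- **Entropy E′** — Shannon entropy (nats) of the vertical height
  profile: vegetated cells are binned at `dz` = 1 m starting at
  `min_height`; ground cells are excluded from the profile, since
  including them would double-count the deep-gap fraction.
- **VCI** — E′ / ln(n_bins) with n_bins the number of 1-m bins spanning
  the occupied height range, so uniform occupancy scales exactly to 1.
- **VAI** — summed leaf-area density over 1-m slices. A CHM carries
  only each column's canopy top, so slice occupancy o_z is the
  fraction of columns whose top lies above the slice bottom, and each
  slice attenuates a downward beam by a Beer–Lambert factor with
  extinction k = 0.5:
  `LAD_z = −ln(1 − o_z (1 − e^{−k dz})) / (k dz)`.
  This per-slice log-ratio form is used rather than a chained
  MacArthur–Horn ratio of cumulative counts because the chained form
  telescopes — its sum depends only on the gap fraction, not on the
  vertical structure — which defeats the purpose of a structure
  metric. The estimator is an approximation; true within-canopy return
  profiles are not recoverable from a surface model.
- **Rumple** — triangulated 3-D canopy surface area over planimetric
  area. Every grid square is split into two triangles along the same
  diagonal; the fixed diagonal makes the value deterministic, and the
  choice of diagonal shifts the area by well under 1% on smooth fields.
- **DGF / CF** — share of pixels with zero canopy height and its
  complement.

CR, entropy, VCI and rumple are invariant to a datum shift (the CHM is
height, not elevation); CR scales linearly with a height rescaling and
DGF/CF are unaffected by it. These properties are enforced by tests.

## Terrain metrics

- **me / E** — mean of per-pixel mean elevations; mean of per-pixel
  max elevations.
- **TR (terrain rugosity)** — population standard deviation of the
  per-pixel (max) elevations, same estimator convention as CR.
- **slope** — Horn 8-neighbor finite-difference gradient per interior
  cell, arctan of the magnitude in degrees, averaged.
- **TRI** — mean absolute elevation difference between each interior
  cell and its eight neighbors, averaged (the Riley root-sum-of-squares
  original is available via `tri_method='rss'`).
- **roughness** — 3×3 window max − min, averaged over interior cells —
  the standard GIS focal-range operator. The secant form 1/cos(slope)
  appears as a separate derived column `roughness_secant`, so both
  published variants of "roughness" are reported without a silent
  choice.

Window metrics use interior cells only (no edge padding — padding
would fabricate elevations) and are computed on the mean-aggregated
grid at each grain, with the per-grain cell spacing entering the
gradient. At grains that leave fewer than 3×3 pixels they are NaN and
drop out of downstream selection. An alternative would be to compute
the windows at the native resolution and average within grain pixels;
the aggregated-grid reading was chosen because the grain sweep is
explicitly about re-gridding before metric computation.

## Combined indices and the multi-trophic diversity index

Site-level metrics are min-max scaled across the site collection to
**[0.1, 1]** (highest site → 1, lowest → 0.1). The 0.1 floor is what
keeps reciprocals finite:

- **RuC** (combined rugosity) = CR_scaled × 1 / TR_scaled. The
  reciprocal encodes the expectation that rugged terrain depresses
  biological structure.
- **RoC** (combined roughness) = CR_scaled × h_scaled × 1 / TR_scaled,
  with h the scaled q95 canopy height, so RoC = RuC × h_scaled.

Per trophic level (plants, beetles, birds), Shannon diversity
H = −Σ p ln p (nats) is computed from taxon counts pooled within a
site, after removing rows with unknown or empty taxon identifiers.
Simpson diversity is reported as the complement 1 − Σ p². Each level's
H is min-max scaled to [0.1, 1] across sites (I′), and

**MDI = (Σ_j I′_j) / n** — the mean of the scaled components over the
n trophic levels. A literal alternative reading ("average, then divide
by the number of levels", i.e. Σ/n²) is available via `form='text'`
for comparison; the mean is the default because it is the citable
formula and keeps the index's range at [0.1, 1] regardless of n.
Species accumulation curves (cumulative distinct taxa over ordered
sampling units, per level and pooled) diagnose whether sites approach
their diversity asymptote; no rarefaction/extrapolation estimators are
attempted.

## Association pipeline

1. **Grain selection.** Spearman's ρ (Pearson correlation of
   mid-ranks) between each metric-at-grain and MDI; p-values by the
   t-approximation (df = n − 2) for n ≥ 10 and exact permutation
   enumeration below. Per metric the grain with the largest |ρ| among
   significant (p ≤ 0.05) entries wins; ties go to the smaller grain
   (cheaper and higher-resolution). No multiplicity correction is
   applied in selection, matching common practice for this screening
   step, but Benjamini–Hochberg adjusted p-values are emitted alongside
   for transparency.
2. **Collinearity filter.** Metrics ranked by |ρ| with MDI and
   accepted greedily; a candidate is rejected when |ρ| ≥ 0.7 with any
   already-accepted metric. Greedy-by-strength is the minimal
   algorithm consistent with "prefer the metric more correlated with
   diversity".
3. **Random forest.** 600 regression trees, 2 candidate predictors per
   split, on structural + climate (MAT, MAP) + geographic
   (latitude, longitude) + mean-elevation features; predictors ranked
   by permutation importance (impurity importance also recorded — both
   are exposed because ensemble importances are convention-dependent).
   Model skill by leave-one-out cross-validation RMSE. Deterministic
   given a seed.
4. **Polynomial model.** OLS of MDI on lon + lon² + MAP + MAP² + MAT,
   refit with combined rugosity added linearly; the R² difference
   quantifies the complexity contribution. The quadratic terms include
   the linear ones because a pure square of longitude is
   location-dependent (a `pure_quadratic` flag restores the literal
   form).
5. **Group tests.** Bray–Curtis dissimilarities between site
   communities; ANOSIM R = (mean between-group rank − mean
   within-group rank)/(M/2) with M = n(n−1)/2 pairwise distances;
   PERMANOVA pseudo-F from the direct between/within partition of
   squared distances. Both tests enumerate all distinct relabelings
   when there are ≤ 10,000 of them (p is then exact) and otherwise use
   random permutations with the conservative add-one convention.

## Synthetic landscapes and communities

The generator exists so every stage can be validated without external
rasters or observational downloads.

- **Terrain**: Gaussian random field synthesized in Fourier space with
  power-law amplitude f^(−β/2) (β = 2.5, a realistic fractal
  roughness), rescaled so the realized standard deviation equals the
  target σ_t exactly, plus a base elevation. Per-site σ_t spans
  0.5–15 m.
- **Canopy**: truncated-normal heights (site means 5–30 m, sd
  0.5–6 m) with a Bernoulli gap fraction of 0.05–0.45, added to the
  DTM.
- **Communities**: per site and trophic level (plant/beetle/bird pools
  of 400/60/90 taxa, sampling depths 2000/600/900 individuals split
  over 5 sampling units), taxon counts are multinomial draws from a
  geometric-series abundance profile with ratio k;
  logit(k) = logit(0.97) + β_c · z, where z is the site's standardized
  combined rugosity. The geometric profile was chosen because its
  Shannon diversity has a closed form, making the planted effect
  calibrable. β_c defaults to **0.055**, calibrated by Monte-Carlo so
  the population Spearman correlation between MDI and RuC is ≈ 0.7 for
  34 sites at the default depths. An optional group shift rotates each
  forest type's taxon dominance order, planting compositional
  differences (visible to Bray–Curtis/ANOSIM) without changing any
  site's diversity.

Default problem sizes — 34 sites of 120 × 120 cells at 1 m — keep a
full synthetic study under a second while leaving every grain of the
default sweep meaningful up to 100 m. The generator does not attempt
spatial community structure, species ranges, observer error, or
forest dynamics; passing recovery tests therefore demonstrates that
the pipeline recovers effects of the kind planted, not that real
landscapes behave this way.

## Numerical conventions

- Quantiles: linear interpolation; rugosities: population (divide by
  s) standard deviations.
- Spearman is undefined for constant inputs and raises.
- Metrics are deterministic; all stochastic components take explicit
  seeds, and CSV floats are written with 10 significant digits so
  repeated runs are byte-identical.
- Degenerate inputs: entropy of a bare site is defined as 0 (with a
  warning); VCI with fewer than two occupied bins is 0; PERMANOVA with
  zero within-group scatter reports an infinite pseudo-F with the
  permutation p still valid.

## Known limitations

- VAI is a surface-model approximation (see above), not a point-cloud
  leaf-area profile.
- Window metrics ignore masked cells by requiring gap-free aggregated
  grids; heavily masked sites should be cropped first.
- The collinearity filter is greedy, not globally optimal; with
  strongly chained correlations a different retained set of equal size
  can exist.
- No spatial autocorrelation correction is applied anywhere in the
  association stage.
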