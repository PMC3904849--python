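# Methods

This note documents the models and procedures implemented in `carbonscape`,
the choices made where the design was genuinely open, and what the
synthetic experiments do and do not demonstrate about real data.

## The upscaling problem

Airborne LiDAR yields accurate carbon-density estimates, but only along
flight strips — here ~8.5% of the study area. Wall-to-wall covariates
(Landsat-style fractional cover, SRTM-style terrain, a categorical habitat
map) exist everywhere. Upscaling means learning the covariate→carbon
relationship on the strips and predicting everywhere else. Carbon density
is derived from mean top-of-canopy height by the fixed allometry
`ACD = 0.3124·TCH^1.854` (Mg C ha⁻¹; TCH in m); the coefficients are frozen
constants with override hooks, since the comparison between upscalers is
insensitive to modest recalibration of this curve.

## The two upscalers

**Stratification.** Continuous covariates are cut into closed-left/
open-right intervals `[x, y)` — a value equal to a breakpoint belongs to
the upper interval. The shipped default scheme allocates 20 intervals:
soil 2, PV 8, NPV 3, elevation 4, slope 2, aspect 1 (breakpoints 5; 85, 88,
90, 91, 92, 93, 94; 6, 13; 136, 193, 443; 1.5; none). Interval combinations
are intersected with the habitat map into packed mixed-radix class
identifiers (bijective and raster-storable). Each class receives the median
observed ACD of its LiDAR-sampled pixels; even sample counts take the mean
of the two middle values (the common statistical convention). Classes with
no samples resolve deterministically: median over sampled pixels sharing
the habitat code, then the global sampled median; the provenance of every
value is recorded in the median table. A quantile mode
(linear-interpolation quantiles, duplicate breakpoints collapsed with a
warning) builds schemes from data instead.

Note an internal tension in the operational variable sets: soil fraction is
binned by the shipped stratification scheme but is sometimes reserved for
the position-feature forest run. Both stratification and the forest include
soil by default here, switchable via `include_soil`.

**Random Forest.** scikit-learn's `RandomForestRegressor` — bootstrap
aggregation of regression trees with per-split feature subsetting.
Defaults follow the regression conventions of the algorithm's reference
implementation: 500 trees, `ceil(p/3)` candidate features per split,
minimum leaf size 5, unlimited depth; all exposed in `RFHyperparams`. The
habitat code is an unordered categorical; because the trees have no native
categorical support it is one-hot expanded when its cardinality exceeds 32
(below that it rides as a bare integer). This matters: how a 134-level
factor enters a tree ensemble materially affects the fit, so the threshold
is a documented, configurable choice.

The second forest run appends four position features: pixel-center
easting/northing and the 45°-clockwise rotation `diagx = (x+y)/√2`,
`diagy = (x−y)/√2`. The rotation is an isometry; its only effect is to give
axis-aligned splits access to diagonal spatial fronts. Both runs reuse an
identical training-pixel set — a uniform without-replacement sample (default
cap 80,000, auto-capped by availability) from LiDAR pixels inside
calibration cells.

## Evaluation protocol

The domain is tiled into a checkerboard of square cells (full-scale
analyses use 50 km; the desk-scale default is 3.75 km on a 30 km domain,
giving an 8×8 board). Cell (0,0) at the NW corner is calibration and roles
alternate with index parity, so 4-adjacent cells always differ; partial
edge cells keep their parity role. Fitting uses LiDAR pixels in calibration
cells only; evaluation uses LiDAR pixels in validation cells only — the
only held-out locations where truth is observed.

Metrics: pooled RMSE; adjusted r² from the OLS regression of observed on
predicted (single predictor, `1−(1−R²)(n−1)/(n−2)`; the regression
direction is a documented convention). "Net bias" per cell is the *mean*
residual (Mg C ha⁻¹ per hectare-pixel) — a mean, not a raw sum, so that a
fixed per-hectare threshold is meaningful across cells of different valid
counts; raw sums are reported alongside, and the Fisher excess kurtosis of
the per-cell bias list summarizes its tails (undefined below 4 cells).
Error as a function of isolation is tabulated by binning pixels on the
exact Euclidean distance transform of the calibration LiDAR coverage
(`scipy.ndimage`); a two-pass chamfer(3,4) approximation is available
behind a flag for parity with approximate-distance workflows, with a ≤10%
error contract verified in tests.

## Residual diagnostics

**Moran's I** with inverse Euclidean distance weights, zero diagonal
(row-standardization off by default, switchable): expectation `−1/(n−1)`,
variance and two-sided p-value from the classical normality approximation
(Cliff–Ord moments). Coincident points are an error — inverse-distance
weights are undefined there. The weight choice mirrors the common default
of the R ecosystem's implementation of this index. Calibration is checked
empirically: on white noise the 5%-level test rejects between 3% and 7% of
the time over 200 replicates.

**Semivariogram.** `γ(h) = Σ(z_i−z_j)²/(2|N(h)|)` over unordered pairs in
15 equal-width lag bins up to (by default) half the maximum pairwise
distance, accumulated in blocks so large subsamples never materialize a
full distance matrix. A Weibull-CDF-shaped curve `γ = a(1−exp(−(h/b)^c))`
is fitted by count-weighted least squares; `h90 = b(ln 10)^{1/c}` satisfies
`γ(h90)=0.9a` exactly and serves as the effective range. Numerical
choices: the fit runs in normalized units (`h/h_max`, `γ/γ_max`) with
multi-start Levenberg–Marquardt (shape starts 0.8/1.0/1.5/2.5 × scale
starts 0.3/0.7), the normalized asymptote bounded to [0, 2] — an asymptote
cannot credibly exceed twice the observed plateau, and leaving it free lets
the shape parameter chase far-lag drift into degenerate fits. Flat
variograms and failed optimizations return a non-convergence flag with NaN
`h90`.

Both diagnostics run on seeded coordinate subsamples (defaults 15,000
residuals for the variogram, 5,000 for Moran's I) that are **shared across
the methods being compared**, so differences between methods are never
artifacts of different locations.

A caution from our own experiments: single-realization range estimation is
fragile when the domain is only ~10 correlation lengths across — fitted
`h90` varied several-fold between seeds. Range-recovery checks therefore
average the empirical variogram over several independent fields and fit
over a window of ~4 correlation lengths; recovery then lands within ~10% of
truth (tested at 25%).

## The synthetic landscape generator

The generator reproduces the *statistical structure* the comparison needs,
not any real geography:

- **Gaussian random fields** with isotropic exponential covariance
  `C(h) = sill·exp(−h/range)`, sampled exactly by circulant embedding on a
  doubled torus (FFT filtering of white noise through the square root of
  the spectrum; tiny negative eigenvalues clipped). Elevation is one such
  field (mean 500 m, SD 250 m, range 5 km); slope/aspect derive from it by
  a Horn 3×3 kernel (replicate-border padding, flat pixels get aspect 0 —
  both documented conventions, the kernel variant being the GIS standard).
- **Fractional cover**: three smooth fields through a softmax ×100, shifted
  so PV dominates (forest landscape); sums are exactly 100 per pixel.
- **Habitat**: a Voronoi mosaic of 134 random centroids — "class membership
  predicts carbon" without modeling real geology.
- **Canopy height** (m):
  `TCH = clip(b0 + β_elev·z(elev) + β_pv·pv + offset[habitat] + GRF + ε, 0, tch_max)`
  with defaults `b0 = 22`, `β_elev = −4` per SD of elevation (higher is
  shorter), `β_pv = 10` per unit PV fraction, habitat offsets ~N(0, 2 m),
  white noise SD 1.5 m, ceiling 50 m — magnitudes chosen once to give
  western-Amazon-like heights (mostly 10–40 m) and mean ACD near
  150 Mg C ha⁻¹.
- **The purely spatial residual**: a GRF with range 3 km and sill 36 m²
  (SD 6 m) added to TCH. This is deliberately the largest single variance
  component: it is carbon variation that *no* covariate carries, so only a
  learner with access to position can capture it. Setting its sill to zero
  makes the covariates explain ≥90% of variance (verified by an oracle
  regression in tests) — the dial that controls how much position
  information is worth.
- **LiDAR coverage**: parallel 2-pixel strips at seeded random offsets
  until coverage is within one percentage point of the 8.5% target.

Determinism: every layer draws from its own named substream
(`SeedSequence([seed, crc32(name)])`), so one master seed reproduces a
landscape bit-for-bit and regenerating one layer never perturbs another.

**What passing tests do not show.** The generator has stationary, isotropic,
Gaussian structure, a noise-free allometry, perfectly co-registered layers
and habitat patches that are convex cells. Real landscapes have
non-stationary variance, anisotropy along rivers and ridges, geolocation
error, cloud gaps and habitat classes with long-range dependence. The
directional conclusions (position features help when spatial residual
variance is large; OOB overstates hold-out skill under autocorrelation)
transfer as mechanisms; the specific RMSE magnitudes do not.

## Problem sizes

Default experiments run at desk scale: 300×300 pixels of 1 ha, 3.75-km
checkerboard cells, training capped by the ~3,800 available calibration
strip pixels, 500 trees. The comparison suite in the tests runs 10 seeds of
this configuration with diagnostic subsamples of 3,000 (variogram) and
1,500 (Moran) — sizes chosen so the full suite runs on a laptop-class
single core in a few minutes while leaving the directional results
unambiguous (10/10 seeds for the method ordering and the OOB gap at these
settings). `ExperimentConfig.full_scale_preset()` records the full-scale
protocol (50-km cells, 80,000 training pixels) for provenance; it is not
exercised by the test suite.

## Known limitations

- Moran's I can marginally exceed [−1, 1] for exotic weight matrices; the
  unit-interval property is asserted empirically on the shipped simulation
  suite, not claimed as a theorem.
- The Weibull variogram fit is a curve summary, not a likelihood-based
  geostatistical model; its `h90` inherits the fragility described above.
- The stratification bin *allocation* (how many intervals each variable
  deserves) is taken as given or set by config; no automatic
  strength-based allocation is attempted.
- Only planar map units are supported — no geographic CRS math,
  reprojection or datum handling.
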