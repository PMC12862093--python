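# Methods

`smveg` implements a basin-scale analysis of the coupling between soil
moisture (SM) and vegetation condition, organized as seven stages: temporal
quality control and compositing of monthly rasters, regression inversion of
layered soil moisture from screened predictors, construction of a composite
vegetation index (VEG) by screened principal-component analysis, per-pixel
rank correlation between the SM and VEG time series, coupling-coordination
scoring and classification, and Gini-importance ranking of environmental
drivers. A synthetic basin generator supplies inputs with the statistical
structure every stage assumes, so the whole chain is testable without any
data download.

## Synthetic basin generator

The generator is first-class, tested code: its outputs define the study
conditions under which the estimators are validated.

**Geometry.** An irregular, connected basin mask on a regular grid (default
cell size 20 m) built by thresholding a smoothed Gaussian random field minus
a radial penalty and keeping the largest connected component; at least half
the grid is inside the basin. All products share one `BasinGeometry`; any
mismatch raises before computation.

**Latent fields.** A wetness field and a vegetation field, each the sum of a
linear north–south trend (south wetter and greener) and a smoothed Gaussian
texture, rescaled to [0, 1]. They share the trend, so moisture and
vegetation are spatially coupled. Interannual variation enters through a
small per-year scalar anomaly (s.d. 0.08) modulated by a smooth pattern.

**Soil samples.** Each site carries three depth layers (0–10, 10–20,
20–30 cm). Physicochemical predictors are drawn from field-plausible ranges
(bulk density BD ∈ [0.9, 1.6] g cm⁻³, capillary porosity P_cap ∈ [30, 60] %,
plus non-capillary porosity, total N/P/K, available K, texture fractions)
with wetness loadings whose signs match the generating equations, so BD and
porosity are the strongest marginal moisture correlates and the nutrients
are consistent but weaker ones. Soil moisture is the per-depth linear truth

    SM(0–10)  = −0.105 + 0.013·P_cap + 0.084·BD
    SM(10–20) = −0.123 + 0.012·P_cap + 0.101·BD + 0.002·TP + 0.016·TK
                + 0.000004·B12 − 0.00001·B6
    SM(20–30) = −0.115 + 0.013·P_cap + 0.091·BD

plus Gaussian noise (default s.d. 0.01), clipped to [0, 1]. With zero noise
the samples close exactly over the equations, which turns parameter-recovery
tests into fixtures of the printed models. Optical band columns are stored
in DN (reflectance × 10⁴) to match the scale of the band coefficients;
radar columns are in dB.

**Bands and vegetation products.** Ten bands per month: B8/B4 are
constructed so their normalized difference equals a target canopy signal
(seasonal factor peaking in July, range 0.35–1), the short-wave infrared
bands (B11, B12) decrease with wetness, and VH/VV backscatter increases with
wetness within [−30, 0] dB. NPP (gC m⁻²) and LAI track the same canopy
field with independent noise, giving the cross-correlated indicator triple
the composite-index stage assumes.

**Drivers.** Eight rasters (population density, elevation, slope, aspect,
mean annual temperature and precipitation, land-surface temperature LST,
potential evapotranspiration PET) with realistic unit ranges. Their texture
uses a fixed smoothing sigma of 2 cells — finer than the wetness field — so
the fields carry enough spatial degrees of freedom for importance recovery
to be identifiable. In the standalone mode a latent coordination field is a
weighted sum of the z-scored drivers plus noise (s.d. 0.35); the default
planted weights are 1 : 1 : 0.5 : 0.25 : … along the order (LST, PET,
precipitation, temperature, elevation, population density, slope, aspect),
which puts LST and PET jointly near half of the recovered Gini importance.
In the anchored mode used by the pipeline the roles invert: each driver is
built to correlate with the basin's wetness/vegetation anchor in proportion
to its planted weight, so a coordination map computed downstream genuinely
depends on the drivers.

What the generator does **not** emulate: radiative transfer, SAR speckle,
cloud geometry, DEM-consistent hydrology, spatially autocorrelated
measurement error, and sensor-specific artifacts. Passing tests therefore
demonstrate that the estimators recover known structure under clean linear
truth with Gaussian noise — not that they would perform equally on real
imagery.

## Temporal quality control

The published sensor-specific cloud/snow rules are not reproducible, so the
module keeps the flag → interpolate → composite shape with a two-parameter
rule: a value is flagged below a radiometric floor (`low_threshold`,
default 0) or, at interior time steps, when it deviates from the mean of
its two temporal neighbours by more than `spike_factor` (default 2) times
the neighbours' absolute difference — so any bump over a flat neighbourhood
is a spike. Endpoints face only the floor test. Flagged values are linearly
interpolated in time; boundary gaps extend the nearest valid value; cells
with fewer than two valid observations become nodata and are logged.
Maximum-value composition takes the cellwise maximum of valid observations.
Seasons are meteorological (spring Mar–May, summer Jun–Aug, autumn Sep–Nov,
winter Dec–Feb), with December assigned to the following year's winter so
multi-year windows stay well defined. QC applies to optical variables and
the vegetation products; radar bands pass through.

## Soil-moisture inversion

Candidates are screened per depth by Pearson correlation with measured SM
(two-sided t test, n−2 df; retain p < 0.05, ranked by |r|; constant columns
are excluded and logged). Sites are split 4:1 into modeling and validation
sets by a seeded shuffle (170 sites → 136/34), all depths of a site on the
same side. Three families are fitted:

- **Stepwise (SMLR)** — forward–backward selection on coefficient p values
  (enter < 0.05, remove > 0.10, the conventional defaults of desktop
  statistics packages). For a single added term the partial-F test equals
  the squared t test, so coefficient p values drive both directions.
  Forward entry stops when the fit is numerically perfect (SSR ≤
  10⁻¹²·SST), since p values computed on zero residuals are floating-point
  noise. If nothing enters, an intercept-only model is returned and flagged.
- **Ridge** — internally standardized predictors, penalty chosen by 5-fold
  cross-validation over a log grid (10⁻⁶…10²), coefficients mapped back to
  the original scale, so penalty → 0 reproduces least squares.
- **PLSR** — component count chosen by 5-fold cross-validated RMSE; at full
  rank the predictions equal least squares. scikit-learn's raw-scale slopes
  are combined with the identity intercept = ȳ − x̄·β.

Validation metrics: RMSE, MAE, MAPE (×100, undefined and warned when a
measured value is 0), R² = 1 − SSE/SST, and the p value of the
prediction–measurement association. The selection rule picks the maximum
validation R² among candidates with RMSE < 0.05, MAE < 0.02 and MAPE in
[0, 20)%; if none passes, the minimum-RMSE model is chosen and flagged.
Ties break by the order SMLR < Ridge < PLSR.

For wall-to-wall prediction, soil-property surfaces are interpolated from
the sample points by inverse-distance weighting (power 2; exact at sites).
The pipeline additionally characterizes each year's property surface
through the moisture-sensitive VH band: surface(year) = IDW base +
slope(property ~ VH at sites) × (VH(year) − VH climatology). This gives
every depth an interannually varying moisture map, mirroring the practice
of representing soil properties through remote-sensing bands. Predictions
are clipped to [0, 1] (volumetric fraction), and nodata propagates.

## Composite vegetation index

Indicators (NPP, LAI, one spectral index chosen among NDVI, EVI, SAVI, DVI,
RVI, ARVI, GNDVI) are z-scored; adequacy is checked by KMO (anti-image
partial correlations; an identity correlation matrix returns 0 with a
warning) and Bartlett's sphericity test (χ² = −(n−1−(2p+5)/6)·ln|R|,
df = p(p−1)/2). The candidate index maximizing KMO is selected among those
with Bartlett p < 0.05, KMO ≥ 0.5 and |r| with LAI or NPP above 0.6; if
none qualifies the best-KMO candidate is used and flagged.

PCA is an eigendecomposition of the correlation matrix. Retention is Kaiser
(eigenvalue > 1) extended while cumulative explained variance is below 90%
— the rule that keeps a second component whose inclusion lifts a ~77%
single-component solution to ~95%. Retained loadings (eigenvector·√λ) are
varimax-rotated with Kaiser normalization (the default rotation of desktop
factor-analysis software); score coefficients follow the regression method,
pinv(R)·rotated loadings — the pseudo-inverse makes degenerate correlation
matrices (perfectly collinear indicators) yield minimum-norm coefficients
instead of failing. Communalities are row sums of squared retained
loadings, invariant under rotation.

Composite weights combine the score-coefficient columns in proportion to
the rotated sums of squared loadings, λ_k/Σλ, and normalize the combined
coefficients to sum to one. A negative combined coefficient is normalized
as-is and flagged. At raster level the indicators are min–max rescaled to
[0, 1] before the weighted sum — z-scores can be negative, and the coupling
model below needs subsystem scores in [0, 1]; this scaling is a design
choice of this package, not a published prescription.

## Per-pixel rank correlation

Spearman's ρ is the Pearson correlation of mid-ranks; significance uses
t = ρ√((n−2)/(1−ρ²)) with n−2 df, two-sided, with |ρ| = 1 mapped to p = 0
and constant series to nodata. The t approximation is inexact for very
short series: at n = 8 (eight annual layers) the exact permutation type-I
rate at nominal 0.05 is 0.0576, so n is always reported alongside p and the
null-calibration test uses 24 time points, where the approximation is
accurate. Pixels are classified at α (default 0.05) into significant
positive/negative and non-significant, with area fractions over the basin.
No across-pixel multiplicity correction is applied by default, matching the
raw p < 0.05 mapping convention; a Benjamini–Hochberg switch exists.

## Coupling coordination

For subsystem scores VEG, SM ∈ [0, 1]: C = 2√(VEG·SM)/(VEG+SM),
T = α·VEG + β·SM with α = β = 0.5 by default, D = √(C·T). C is 1 exactly at
balance, 0 when either subsystem vanishes, and nodata when both are 0 (a
0/0 with no ecological meaning). A harmonic-mean form of C is available for
sensitivity analysis. D is binned into five ordinal classes on half-open
intervals (0, 0.2] … (0.8, 1.0] — Extreme Disorder, Mild Disorder, Barely
Coordinated, Moderately Coordinated, Highly Coordinated — with D = 0
assigned to the lowest class by convention and logged. Whether to min–max
rescale the inputs first materially shifts class fractions; the pipeline
rescales by default and the choice is configurable and logged.

## Driver importance

D is discretized into its five classes (keeping the analysis within the
classification form of the Gini equations; a variance-impurity regression
mode on raw D is available). A bootstrap random forest (default 500 trees
in the CLI, 200 in the pipeline; mtry = ⌊√8⌋ = 2; minimum leaf 5; unlimited
depth) is grown by scikit-learn's CART; the importance accumulation is done
here by walking each fitted tree: per split, gain = Gini(parent) −
(n_l/n)·Gini(left) − (n_r/n)·Gini(right), summed per feature over all
nodes and trees and normalized to shares. Count-weighting the children is
the only reading that keeps every gain nonnegative, as an importance
decomposition requires; the library's built-in importances are not used
because they additionally weight each gain by the node population. Pixel
tables are subsampled (seeded) to bound memory. Ranking consistency across
depth layers is summarized by pairwise Kendall τ.

## Numerical choices and degenerate inputs

- Zero denominators in spectral indices become nodata rather than ±inf.
- Raster values are float64 in memory, float32 on disk (TIFF, nodata −9999,
  geometry as JSON in the image description tag).
- IDW distances are floored at 10⁻¹² m with exact site values restored.
- Correlation-matrix eigenvalues are clipped at 0; component signs follow
  the dominant loading direction; rotated components are ordered by their
  sums of squared loadings.
- The D map may carry isolated extra nodata cells relative to the drivers
  (min–max rescaling guarantees a zero cell); the driver table requires
  only frame agreement and drops incomplete pixels.
- Seeds: one global seed fans out to per-stage child generators via CRC32
  tags, so stages reproduce independently and runs are bit-identical.

## Problem sizes

The pipeline defaults — a 48×48 basin at 20 m, 120 sites × 3 depths, 8
years × 12 months, 200-tree forests on ≤ 20 000 pixels — are scaled-down
analogues of a ~1900 km² basin chosen so a full run takes seconds and the
statistical properties under test (recovery, calibration, planted-structure
detection) are already identifiable at this size. Null-calibration and
recovery tests state their own sizes (500 screening replicates, 100
recovery seeds, 10 forest seeds).

## Known limitations

- The inversion validates on synthetic truth; its published-data analogue
  (R² > 0.95 on field samples) is not reproducible without the field data.
- The t-based Spearman p is approximate for the 8-point annual series; the
  module reports n rather than gating on it.
- Stepwise selection is path-dependent; its equivalence to exhaustive
  stable-subset search holds on well-separated designs with equal
  entry/removal gates, which is how the oracle test frames it.
- KMO of an equicorrelated triple saturates at 0.8 as r → 1; values near 1
  require more indicators. The 0.5 adequacy gate is unaffected.
- IDW is a deliberate, simple spatializer; kriging and other geostatistical
  models are out of scope.
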