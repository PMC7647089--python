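# Methods

## The bookkeeping model

The model assigns carbon by land-cover class and updates it only on class
transitions. Its assumptions, implemented as stated rather than improved:

1. every class's reservoirs (AGB, BGB, SCS₁₀₀) are at statistical
   equilibrium — a pixel that converts and later converts back returns to the
   original class's distribution (exactly to its mean in expected mode);
2. natural-cover soil stocks do not drift over the study window;
3. rainfed and irrigated cropland are annual crops with fixed BGB/AGB ratios
   baked into the parameter table;
4. reservoirs do not interact: a class change redraws AGB, BGB and SCS₁₀₀
   jointly but independently, with no cross-reservoir correlation.

Per-pixel values are resampled with replacement from precomputed class pools
(size `n_pop = 10⁵` by default) rather than drawn fresh from the normal —
equivalent in distribution, cheaper, and it makes the "values never leave the
class bounds" contract trivially auditable. Redraw randomness is organised as
counter-based per-year fields: for each (year, reservoir) a full grid of pool
indices is generated from a Philox stream keyed on (root seed, year,
reservoir), so a pixel's redraw depends only on its position, the year and its
new class — results are independent of traversal order and of which other
pixels changed, and adding a class perturbs nothing (pool substreams are keyed
by a CRC of the class/reservoir name).

Water and urban/farm-building classes carry zero carbon but occupy area; they
are included in area accounting and in the per-hectare denominator, excluded
from carbon means. Nodata in the class raster is nodata (NaN) in every carbon
map and excluded from aggregation. Pixel area comes from the raster's affine
transform (30 m ⇒ 0.09 ha), never hard-coded.

Transitions among natural classes (e.g. savanna ↔ grassland) redraw all three
reservoirs like any other change; since both share the pooled Cerrado soil
parameters, the soil redraw is distribution-neutral.

## Soil stocks and the equivalent-mass correction

Layer stock: `S = 0.1 ρ c h` (ρ g cm⁻³, c g kg⁻¹, h cm) in Mg-C ha⁻¹; layer
soil mass: `M = 100 ρ h` Mg ha⁻¹. The sampling design has seven layers (0–5,
5–10, 10–15, 15–20, 20–40, 40–60, 60–100 cm); the three deep layers were
sampled at mid-points and are treated as homogeneous, so properties are
constant within a layer and a depth inside a layer pro-rates carbon linearly
by thickness.

The equivalent-mass stock accumulates whole layers while cumulative mass stays
below the reference mass and adds the mass-fraction of the straddling layer.
The reference mass defaults to the mean cumulative mass over all native-cover
(FOR + CDO) profiles at the nominal depth — the method's reference is
configurable by class set and recorded in the output metadata. A profile
lighter than the reference mass yields a flagged (`extrapolated`) result
rather than an extrapolation. Exactness: because properties are
piecewise-constant, the implementation is closed-form; a fine-slab numerical
integration is kept in the tests as an independent oracle (agreement < 0.1%).

Group statistics use the exact t-based half-width `t₍₁₋α/2,n−1₎·s/√n`. The
reference study's published CI column is internally inconsistent for some
classes (its pasture row prints ci = sd); this package implements the exact
formula and does not reproduce those cells. Published pairwise p-values are
likewise not derivable from the printed summaries under either t-variant, so
the t-test layer is validated by calibration (type-I error at nominal level)
and by construction instead. Group sizes are always taken from the data.

Percentage differences come in two conventions — denominator the native mean
(`baseline_native`) or the agricultural mean (`baseline_agricultural`) — which
satisfy `(1 + p_nat/100)(1 − p_agr/100) = 1`; the convention is always
recorded in the output because the reference tables mix both (topsoil column
agricultural-based, full-profile column native-based).

Two t-test variants exist in two places with different defaults, both
deliberate: soil class comparisons default to Welch (field groups have
visibly unequal variances), period comparisons default to pooled Student
(matching the published degrees of freedom, 12 for 7 vs 7 years and 13 for
7 vs 8).

## Parameter pools

Truncation bounds are μ ± kσ. The default k = 0.95 reproduces the published
min/max of the reference parameter table for the soil block, the BGB block and
most AGB rows; the published forest-AGB row alone corresponds to k ≈ 1.96 (the
central-95% convention the table's footnote describes), and two rows (pasture
AGB, mosaic AGB) are internally inconsistent under any single k. The shipped
CSV therefore stores means and standard deviations verbatim and derives
bounds from k; users can supply explicit min/max columns to override. The
mosaic class (RAG_PAST) is parameterised as the arithmetic mean of cropland
and pasture, as in the source table.

Out-of-bounds draws are rejection-resampled, not clipped, so pools have no
probability atoms at the bounds. With symmetric bounds the truncated mean
equals μ; pool moments are tested against closed-form truncated-normal
moments.

## Synthetic data

The land-cover generator targets per-class area fractions interpolated
linearly between anchor years (defaults proportional to the study region's
1990/1997/2004/2011/2018 class areas over 13.40 Mha, which sum to the full
region — water/urban default to zero area). Fractions become integer pixel
targets by largest-remainder rounding, so counts are exact (±0 pixels) and
conserved: pixels gained by growing classes equal pixels lost by donors each
year. The initial map is a competitive multi-seed region growing; later years
convert contiguous patches, growing from the expanding class's boundary into
whichever classes hold surplus area. This patchiness (rather than
salt-and-pepper reassignment) is what exercises the model's bit-stability
rule on realistic frontiers. It makes no geomorphological claim.

Soil profiles: organic carbon decays exponentially with depth (rate
0.02 cm⁻¹), bulk density increases with depth (0.25 g cm⁻³ m⁻¹) from a
class-specific surface value, optionally inflated for agricultural compaction.
Each profile's 0–100 cm fixed-depth stock is drawn from a **moment-matched
lognormal** (parameters chosen so the mean and sd equal the class targets
exactly) and the surface concentration is solved so the seven-layer integral
hits that draw exactly. A lognormal is used instead of a positivity-truncated
normal because truncating a normal with CV ≈ 0.5 at zero biases the mean by
≈ 3 Mg-C ha⁻¹ — comparable to one standard error at n = 200 — whereas the
lognormal keeps both target moments exact, stays positive, and matches the
right skew of field soil-stock distributions. What passing recovery tests
shows is that the statistical machinery is unbiased at the study's effect
sizes; the generator does not emulate spatial autocorrelation between sites,
measurement error structure, or any pedological depth law beyond the
monotonic shapes above, so it cannot validate those aspects of real
campaigns.

## Numerical and scale choices

* Default synthetic problem sizes — 300×300 pixels × 29 years for
  raster-series checks, 200 profiles/class for recovery, 10⁴ replicates for
  t-test calibration — were chosen as the smallest sizes at which the 3-SE
  acceptance bands are meaningfully tight; all complete in seconds to a few
  minutes on one core.
* Stochastic↔expected consistency uses the standard error
  `SE² = a²(n_px + n_px²/n_pop)·σ²_pool` (a = pixel area in ha): the second
  term accounts for the shared finite-pool mean, which at n_px ≈ n_pop is not
  negligible.
* All randomness flows from a single root seed through `numpy`
  `SeedSequence` substreams; same seed ⇒ bit-identical rasters, pools, states
  and reports.
* Rasters are stored as plain-text ESRI ASCII grids with a JSON sidecar for
  provenance (year, CRS, seed, mode, parameter hash); float grids round-trip
  losslessly at float32 precision. All rasters of a series must share
  geometry; there is no reprojection.
* Degenerate inputs: groups of n < 2 and zero-variance test pairs are flagged,
  never silently dropped; profiles with missing bulk density are rejected with
  a warning (no pedotransfer imputation); reference masses exceeding a
  profile's total mass refuse extrapolation.

## Known limitations

* No transient carbon dynamics: conversion moves a pixel instantaneously to
  the new class's equilibrium distribution, so short-lived classes are
  over-resolved and slow soil responses are not represented.
* Per-class uncertainty columns in regional-total reports are parameter
  spreads passed through, not sampling errors of the totals (which would be
  near zero at ~10⁷ pixels).
* The expected mode is exact only for totals; nonlinear statistics of pixel
  distributions (quantiles, exceedance areas) require stochastic mode.
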