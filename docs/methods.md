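# Methods

This note documents the models, parameter choices and numerical decisions
behind `tusktrack`, and what the synthetic-data tests do and do not
demonstrate about real tracking data.

## Data model

Raw input is a per-individual table of hourly GPS *attempts*: every row has
a timestamp, successful rows also carry lon/lat. Tusk-mounted loggers only
obtain fixes when the antenna is dry, so 25–66 % of attempts fail and the
successful series is irregular, with a median gap of 2–4 h and occasional
gaps of hundreds of hours (download outages, fouling, behaviour).

All planar work happens in a spherical azimuthal-equidistant projection
centred on the data centroid. At 74–82° N geographic-coordinate arithmetic
is unusable; the azimuthal-equidistant choice makes radial distances from
the centre exact, so kernel bandwidths, buffer radii and grid cells are
metrically honest across a study area a few hundred km wide. Distances
quoted in km are great-circle on a sphere of radius 6371 km.

## Preprocessing

Screening removes the second of two positions sharing a timestamp, and
positions implying > 10 m/s against both neighbours (at the series ends the
single neighbour decides), repeated to a fixed point. The 10 m/s screen is
a reproducible surrogate for visual outlier inspection; walruses do not
exceed ~2 m/s sustained, so the screen only catches gross position errors.

Regularization estimates a position every 3 h by time-weighted linear
interpolation along the projected fix path, after an iterative forward
speed filter at 2 m/s. The 3-h lattice is anchored at the first successful
fix. Nothing is estimated across gaps longer than 96 h; the segment index
increments there and all downstream analyses treat segments independently.
Linear interpolation rather than a state-space smoother is a deliberate
simplification: GPS error is tens of metres against 3-h displacements of
kilometres, so smoothing would move estimates by far less than any analysis
grid cell. A correlated-random-walk smoother can replace the interpolator
behind the same interface if sub-cell accuracy is ever needed. Because the
interpolated path is a chord of the observed one, within-segment step
speeds never exceed the (speed-filtered) fix-to-fix speeds.

Tusk volume treats the tusk as a cone, `V = ⅓ π r² h` with
`r = girth/(2π)`, reported to 0.1 cm³.

## Time spent in area

Each 3-h step is a straight planar segment; its duration is apportioned to
grid cells (default 3 × 3 km) in proportion to the segment length inside
each cell, computed from the exact parametric crossings of the cell edges.
Stationary steps accrue wholly to their cell. Cells are half-open, so a
point on a shared edge belongs to the higher-index cell deterministically.
Grid totals therefore equal the summed within-segment duration to floating
point accuracy — a property the tests assert at 1e-6 relative. For maps,
visited cells are classified by percentile rank among the individual's
visited cells, and the 99th percentile (linear interpolation) is reported.

## Migration phenology

The individual distance threshold is the mean great-circle distance from
the tagging site to all 3-h positions. Runs of positions beyond the
threshold lasting ≥ 14 × 24 h (elapsed time, not calendar days) are winter
residence; shorter excursions are scouting trips and count as summer
habitat. An optional cap bounds the threshold for extreme rangers (the
analysis this package reimplements capped one animal's 283-km threshold at
the 163-km maximum of the others); the cap is a per-individual
configuration parameter, not a default. Winter onsets outside December–
April produce a warning, not an error, so that the generator can stress the
rule.

Because core areas require seasons and migration buffers require core
areas, segmentation runs in two passes: pass 1 classifies seasons from the
threshold alone; pass 2 computes seasonal 50 % UDs from those labels and
refines migration timing with 10-km buffers around them. A migration runs
from the last position inside the buffered origin region to the first
position inside the buffered destination region; duration and path
distance use the interpolated track (robust to gaps), while yearly
cumulative distances use the raw fixes (interpolation smooths and would
bias distance downward — the tests assert raw ≥ interpolated). Events
longer than 40 days are flagged as outliers and excluded from labelling,
mirroring the exclusion of one 77.6-day event in the source analysis.

## Home ranges and overlap

UDs are Gaussian product-kernel densities on a 500-m grid with the ad hoc
bivariate reference bandwidth `h_ref = ½(sd_x + sd_y) n^(−1/6)` (the
convention of the standard home-range packages; the choice matters mainly
for absolute area sizes, not for overlap). Cell masses are normalized to
sum to one; isopleth regions take cells in decreasing density until the
target mass is reached, so the region is minimal by construction and areas
are cell count × cell area.

Interannual fidelity uses the one-way index
`PHR_{i,i+1}(level) = Σ mass of UD_{i+1} over the level-region of year i`,
rescaled by 1/level so that 50 % and 95 % values are comparable. The index
is asymmetric by design and only the forward direction is reported. Note
that the raw index is bounded by 1, not by the level: it equals the level
exactly only in the identity case. Synthetic animals that re-use a range
perfectly can therefore rescale above 1; field data rarely do.

50 % MCP centroids peel positions by distance to their mean, keep the
closest half, and take the convex-hull centroid. Seasons shorter than
30 × 24 h are excluded from UD estimation; incomplete seasons may still
contribute centroids when no complete season exists.

## Environment

Day length comes from the sunrise equation with the standard NOAA
declination series and a rise/set altitude of −0.833° (refraction plus
solar semidiameter); polar day/night saturate at 24/0 h. Note the
refraction correction lengthens days in both hemispheres, so
`daylight(φ) + daylight(−φ)` slightly exceeds 24 h away from the poles.
Day length is evaluated at the animal's position of the day.

Ice charts are category-labelled polygons; the six operational classes map
to mid-range concentrations: Open water 5 %, Very Open Ice Drift 25 %,
Open Ice Drift 55 %, Close Ice Drift 80 %, Very Close Ice Drift 95 %, Fast
Ice 100 %. Charts are queried on a fixed 0.05° lattice: a position is
snapped to its cell centre and takes the category of the containing
polygon — the exact value a rasterized chart would hold, without
materialising rasters for thousands of chart days. Missing chart days use
the nearest available date within 7 days; ties resolve to the earlier
chart. Rasters (bathymetry, TSA, UDs) are written as ESRI ASCII grids —
plain text readable by any GIS.

The pre-migration model asks whether daily mean ice concentration along
the animal's positions differs between 14–8 days (period A) and 7–1 days
(period B) before the winter departure. Day −k covers
[departure − k d, departure − (k−1) d); day −8 belongs to A, day −7 to B.
The model is `y ~ year + period` with a random intercept per animal, AR1
residual correlation on day lag within each individual-year series and a
variance multiplier per year, fitted by restricted maximum likelihood with
the residual scale profiled analytically and the remaining parameters
(AR1, intercept-variance ratio, year weights) optimized by Nelder–Mead.
Inference is Wald-t with residual degrees of freedom n − p (the df
convention of the analogous field models is package-specific; residual df
is the transparent choice). Where concentrations are small and skewed the
response can be arcsine-square-root transformed (`transform=
"arcsine_sqrt"`), as used for the northern group in the source analysis;
the raw percentage scale is the default. Simulation at 8 animals × 3 years
× 14 days puts the period test's type-I error at the nominal 0.05 within
Monte-Carlo error.

## Move persistence

The index γ_t ∈ (0, 1) is the time-varying autocorrelation of successive
3-h displacements under `d_t = γ_t d_{t−1} + ε_t`, ε isotropic Gaussian,
with logit(γ_t) following a Gaussian random walk. Estimation maximizes the
penalized likelihood over the logit path (the posterior mode) with the
observation variance profiled in closed form; the random-walk variance is
selected by a Laplace-approximate marginal likelihood over a log-spaced
grid (0.02–2 per step, floor 1e-6), using the Gauss–Newton tridiagonal
Hessian for the determinant. Segments are estimated independently and
never couple across > 96-h gaps; all-stationary segments yield missing
values rather than arbitrary γ.

The regression layer models logit(γ_t) against ice concentration (scaled
to [0, 1]) and log-depth (floored at 1 m) with per-individual random
intercepts/slopes, fitted by maximum likelihood via statsmodels MixedLM
and ranked by AIC across nine candidate formulas (fixed subsets of
{ice, depth, ice×depth} with random structures up to (ice + depth | id)).
Candidates that fail to converge are dropped from the ranking. Estimation
is two-stage (γ_t per track, then the mixed model) rather than joint; this
keeps each stage testable against its own ground truth at the cost of
ignoring γ-estimation uncertainty in the regression — a limitation shared
with any plug-in approach.

## Synthetic data: what it emulates, and what it does not

The generator's movement model is a first-difference correlated random
walk whose persistence switches between a resident level (0.30) and a
transit level (0.90) by behavioural phase — deliberately the generative
dual of the γ_t estimator. Residency adds a homeward drift (12 % of the
offset per 3-h step, capped at 4 km) around the seasonal centre; migration
adds a directed drift toward the destination at the speed implied by the
scheduled duration; innovations have SD 1.3 km per step scaled by
√(1 − γ²). Steps are capped just under the 2 m/s regularization constraint.
Scenario defaults mirror the study conditions: two seasonal ranges 170–430
km apart, departures late October–January, returns March–May, migrations
of 6–17 days, sub-14-day scouting trips in ~40 % of animals, track spans
of 1–6 years.

Sampling: hourly attempts gated by a two-state haul-out/at-sea Markov
chain (stationary haul-out fraction 0.2, mean bout 3 h — configuration
guesses, as no haul-out statistics are reported for these tags). Hauled
attempts fail at half the net rate (posture can block the sky view),
at-sea attempts make up the remainder so the net failure equals the
configured `fix_fail_prob` (default 0.45, inside the reported 25–66 %).
Under these defaults, 8–17 fixes succeed on ≥ 90 % of days and the median
gap is ~3 h, matching the reported deployment statistics. Truth output
records the latent path, per-step season and γ, and for each migration
both the phase-switch time and the core-area crossing times (15-km radius
of the seasonal centre) — the latter being what a buffer-based detector
estimates.

The ice generator produces one chart per day from a latent concentration
`base + gradient·(lat − lat_min) + amplitude·cos(2π(doy − peak)/365) +
AR1 daily noise`, quantized into the six classes at fixed edges; because
the noise is spatially uniform, each chart is an exact stack of
latitude-band polygons. Bathymetry is a deterministic exponential shelf
profile (20 m at the synthetic southern coast to ~600 m offshore).

What passing the synthetic tests does **not** show: robustness to real GPS
error structure (multipath, hexagonal dilution near haul-outs), to
non-Gaussian step distributions, to ice charts with complex polygon
topology (leads, polynyas), or to behaviour outside the two-range
migration template (nomadism, mid-winter range shifts). The generator's
seasonal schedule is also more regular than real phenology; recovery
errors on field data will be larger than the synthetic medians.

## Numerical conventions

* Timestamps are UTC; intervals are half-open [start, end).
* Grid cells are half-open in both axes; edge points belong to the
  higher-index cell.
* Chart-date ties resolve to the earlier chart.
* γ values are clipped to (1e-9, 1 − 1e-9); logit round-trips to 1e-12.
* All generators and the pipeline are deterministic functions of their
  seed; a single top-level seed spawns per-individual streams.
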