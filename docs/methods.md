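# Methods

## Scope and data model

The package analyzes how continental-shelf seafloor area is distributed
over depth and latitude, and what that geometry implies for species
shifting deeper and poleward. Its central data structure is the
**shelf cell table**: one record per retained grid cell with center
coordinates, depth (m, positive down) and geodesic area (km²). A cell is
retained iff its elevation is strictly negative (the low-water mark is the
shelf's upper bound, so elevation exactly 0 is land), its depth does not
exceed the 2000 m cap (misclassification margin over the ~200 m typical
shelf), and its **center** lies inside the region ∩ shelf polygon
(boundary counts as inside). Cells dropped by the depth cap are counted
after polygon masking and logged.

Cell areas use the spherical-cap formula on the authalic sphere,
`A = R²·Δλ·(sin φ_top − sin φ_bot)` with R = 6371.0 km — exact on the
sphere, constant along a latitude row, strictly decreasing with |φ| and
summing to 4πR² over a global grid (asserted to 1e−6 relative). No
reprojection engine is included; the analytic invariants replace a
projected-polygon cross-check.

Raster input is netCDF (CF conventions, read through xarray with the scipy
backend; files are written as NETCDF3 classic) or GeoTIFF with basic
georeferencing (ModelPixelScale/ModelTiepoint tags; a projected-CRS geokey
is rejected with an explicit error). Coordinates are treated as cell
centers; grid-registered sources are thereby shifted half a cell, which is
logged. Polygons are GeoJSON (shapely); invalid geometries are repaired
with `make_valid`, and polygons extending past ±180° are wrapped back into
[−180, 180] before masking.

## Hypsometry

The hypsometric curve accrues cell area into half-open depth bins
`[lower, lower + width)` (default 1 m); the final bin is closed at the
depth cap so a cell at exactly 2000 m is kept. Depth bands (default 15 m —
the approximate expected depth shift over four decades) tile upward from
0 m with the same convention. Conservation (Σ bins = Σ bands = Σ cell
areas), refinement consistency (1 m bins aggregate exactly to 15 m bands)
and degree-1 homogeneity in the area weights are property-tested. Mean
depth is the area-weighted arithmetic mean. Band-transition deltas report
A_next − A_current and the ratio per adjacent pair shallow→deep, with the
ratio flagged undefined when the source band is empty.

## Depth-distribution classification

Categories: Uniform, Multimodal, Shallow-Dominant, Mid-Dominant,
Deep-Dominant, assigned sequentially:

1. **Uniform** if the KS test against a uniform depth distribution cannot
   reject (p > α = .05);
2. else **Multimodal** if Hartigan's dip D > 0.01 **and** its Monte-Carlo
   p < α;
3. else by area-weighted skewness g₁ = m₃/m₂^{3/2}: > +1
   Shallow-Dominant, < −1 Deep-Dominant, otherwise Mid-Dominant. A
   sensitivity variant uses ±0.5; relaxing the thresholds can only move
   regions out of Mid-Dominant, never into it.

**The test sample.** The KS and dip tests need a sample, but the natural
input is an area-weighted cell table. The bridge is a *deterministic
area-weighted quantile resample*: value i (1…n, default n = 10 000) is the
depth at probability (i − 0.5)/n of the weighted empirical depth CDF
(inverse ECDF, step interpolation). This honors area weighting, is
reproducible without randomness, and fixes the effective sample size so
the constant dip threshold 0.01 sits roughly at twice the 95% uniform
critical dip at n = 10 000 (≈ 0.005, checked by simulation) — the joint
rule then behaves as intended. The resample size is configuration, not a
hidden constant: with raw per-cell samples in the millions the KS test
would reject uniformity almost always. Skewness is computed on the full
weighted cell table, not the resample, to avoid discretization loss.

**KS details.** D is the sup-distance between the sample ECDF and the
uniform CDF over an estimated range. The range is the sample extremes
extended by half a mean gap per end (`[min − r/(2n−2), max + r/(2n−2)]`,
r = max − min): under this midpoint plotting-position correction a perfect
quantile sample attains the minimal D = 1/(2n) exactly, rather than being
penalized for its estimated endpoints. The p-value uses the asymptotic
Kolmogorov distribution with Stephens' finite-n factor
(√n + 0.12 + 0.11/√n). Estimated endpoints still bias the test toward
conservatism; this is accepted and only affects rule 1.

**Dip details.** The dip statistic is half the minimal sup-norm distance
between the ECDF and the class of unimodal CDFs (convex below the mode,
concave above, atom permitted at the mode); it lies in [1/(2n), 1/4], is
exactly 1/(2n) for n = 2, 3, and handles ties (ECDF jumps > 1/n). The
implementation is the classic iterative greatest-convex-minorant /
least-concave-majorant algorithm on a shrinking modal interval, compiled
with numba. It is validated against an independent brute-force oracle that
minimizes the distance over unimodal CDFs directly by linear programming
(per candidate mode position, the chord slopes of a piecewise-linear
candidate must rise then fall — all constraints linear), with exact
agreement (1e−10) on random small-n samples including heavy ties. The
p-value is Monte Carlo: p = (1 + #{dip(U(0,1)ⁿ) ≥ D})/(B + 1) with
B = 2000 and a fixed seed; the null table is cached per (n, B, seed), so a
batch of regions with a common resample size costs one simulation.

Skew, KS D and dip D are affine-invariant in depth, so classification is
unchanged under depth rescaling (property-tested).

## Latitude profiles

Cell areas accrue to half-open 2° bins aligned to even integer latitudes
(`floor(lat/2)·2` on the signed latitude, so [0, 2) is Northern and
[−2, 0) Southern); empty interior bins are emitted with zero area so
transitions see gaps. Each coastline is analyzed per hemisphere,
equator → pole. A poleward step with area ratio ≥ 2 is an *expansion*,
≤ 0.5 a *contraction* (exactly 0.5 flags); steps out of a zero-area bin
are undefined and excluded from the summary percentages. The trend is OLS
of bin area on **absolute** mid-latitude (scipy `linregress`), so a
positive slope means "more area poleward" in both hemispheres; a constant
series returns slope 0 with p = 1 rather than an indeterminate t-ratio.
Flags and percent changes are scale-invariant, and mirroring a series into
the other hemisphere preserves |slope|, p and the flag sequence.

## Species–area projections

Richness changes use the power law S = C·Aᶻ with C = 1 (only relative
changes are reported, and C cancels): ΔS% = 100·((A₁/A₀)ᶻ − 1), strictly
increasing in the ratio, amplified by z (bigger |ΔS%| at z = 0.62 than
0.38 than 0.175 on either side of ratio 1), equal to −100% exactly when
the target area is zero, and reported uncapped above +100%. Projections
are produced per poleward 2° transition and per 15 m depth-band transition
at all configured z values.

## Synthetic data: what it emulates and what it does not

`synth_bathymetry` assigns depths by the target inverse CDF at
area-weighted midpoint probabilities over a seeded permutation of cells.
The realized (depth, area) multiset therefore matches the target
distribution to within one cell weight at any latitude — every downstream
statistic depends only on that multiset, never on spatial arrangement — and
identical spec + seed gives a bit-identical grid. Targets are uniform,
beta(α, β) and beta mixtures on [0, 2000] m; category, skewness
(2(β−α)√(α+β+1)/((α+β+2)√(αβ)), mixtures via raw moments) and expected
classification come in closed form. Test grids sit within ±5° of the
equator so row areas are nearly equal, but the area-weighted assignment
keeps the closed forms valid at mid-latitudes too (tested at 40–60°).

`synth_coastline` carves a shelf strip (depth 100 m) of prescribed width
in km east of a meridional coast, with piecewise-constant or linearly
ramped width profiles. The per-row strip cell count is
`round(width / (R·cos φ·Δλ))`; expected 2° bin areas are the corresponding
`k·A(φ)` sums, computed from the profile alone, and the pipeline
reproduces them exactly (it sums the same cells). Declared
expansion/contraction events are width steps with ratio ≥ 2 or ≤ 0.5 at an
even-latitude boundary. Because rounding can bias a row by half a cell,
randomized test profiles keep strips ≥ ~13 cells wide at the test
resolution (2′), so a genuine ×2.2 step cannot be blurred below the ×2
flag threshold; narrower strips would need finer grids. The analytic OLS
slope comes from the continuous meridional integral ∫w(φ)·R dφ per bin.

The generators target statistical structure only: no canyons, banks,
fractal shelf edges, spatially correlated noise, or data gaps. Passing
recovery tests therefore demonstrates correctness of the statistics and
plumbing under known conditions, not robustness to real-data artifacts
(nodata seams, datum quirks, polygon topology errors beyond simple
self-intersections).

## Problem sizes and numerical choices

Tests and the acceptance script run on deliberately modest sizes chosen to
exercise every code path with comfortable statistical margins: 100×100
cells per classification grid (20 seeded grids per category, recovery
≥ 95% required, observed 100%), dip-oracle comparison at n ≤ 8 over 100
random samples plus spot checks to n = 45, 50 seeded coastlines of
600×165 cells at 2′ resolution for flag recovery, and a 1320×120 ramp
coastline for the 1%-slope check (observed error ~0.005%). Degenerate
inputs raise typed errors (empty tables, zero variance, single bins);
empty polygon intersections warn and return empty tables rather than
raising. All randomness flows from explicit seeds; reruns are
byte-identical.

Known limitations: no ESRI Shapefile reader (convert to GeoJSON first);
no fractional cell-polygon overlap (cell-center membership only, matching
common raster-package semantics); the KS null range is estimated from the
sample rather than fixed a priori; Monte-Carlo dip p-values are granular
at 1/(B+1); and real-data category shares depend on the resample size n,
which is deliberately exposed as configuration.
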