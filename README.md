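# shelfhypso

Continental-shelf hypsometry for range-shift ecology: how much seabed area
will marine species find as they move **deeper** and **poleward** under
climate change?

Marine species on continental shelves track temperature by shifting their
ranges down-slope and toward the poles, but the seafloor area available at
the destination depends entirely on regional bathymetry. `shelfhypso` turns
a gridded elevation model plus region/shelf polygons into:

* **Area-weighted hypsometric curves** — shelf area (km²) per 1 m depth bin
  for each marine region (e.g. Large Marine Ecosystems), with geodesic cell
  areas `A = R²·Δλ·(sin φ_top − sin φ_bot)` on the authalic sphere
  (R = 6371 km) and a 2000 m depth cap.
* **A five-way depth-distribution classification** — Uniform, Multimodal,
  Shallow-Dominant, Mid-Dominant, Deep-Dominant — via a fixed decision
  tree: a Kolmogorov–Smirnov test of uniformity, then Hartigan's dip test
  of unimodality (D > 0.01 and Monte-Carlo p < .05 ⇒ Multimodal), then
  area-weighted skewness g₁ with thresholds ±1 (±0.5 sensitivity variant).
  The dip statistic — the minimal sup-norm distance between the empirical
  CDF and the nearest unimodal CDF — is implemented from scratch with the
  greatest-convex-minorant / least-concave-majorant iteration.
* **Latitudinal shelf-area profiles** — area per 2° latitude bin along a
  coastline, flagged where a poleward step at least doubles (*expansion*)
  or halves (*contraction*) the area (motivated by the IUCN 50%
  habitat-loss criterion), plus an OLS trend of area on |latitude|.
* **Species–area projections** — predicted percent richness change
  `ΔS% = 100·((A₁/A₀)^z − 1)` for a 2° poleward or 15 m depthward shift,
  with z = 0.38 (marine-fish mean) and 0.175/0.62 bounds.

A synthetic-data module generates bathymetry grids whose area-weighted
depth distribution follows prescribed shapes (uniform, beta, beta mixture)
and coastline strips with piecewise width profiles — all with closed-form
ground truth — so the entire pipeline is testable without any download.

## Worked example

Generate synthetic inputs (four regions, one per recoverable category, and
one coastline with a built-in width doubling at 20°N), then run both
analyses:

```sh
shelfhypso synth --out fixtures --seed 3
shelfhypso depth-analysis fixtures/config.yaml --out results_depth --seed 3
shelfhypso latitude-analysis fixtures/config_coastline.yaml --out results_lat --seed 3
```

The depth analysis prints the category-share table:

```
        category  count  pct_of_classified  pct_of_classified_rounded  pct_of_all_regions
Shallow-Dominant      1               25.0                         25                25.0
    Mid-Dominant      1               25.0                         25                25.0
   Deep-Dominant      0                0.0                          0                 0.0
         Uniform      1               25.0                         25                25.0
      Multimodal      1               25.0                         25                25.0
```

Each synthetic region lands in its generator's true category: the
Beta(1.5, 12) grid (skew 1.216, mass piled at shallow depths) is
Shallow-Dominant, the symmetric Beta(2, 2) grid is Mid-Dominant, the
50/50 Beta(5, 45) + Beta(45, 5) mixture trips the dip test (D ≈ 0.19,
p = 5×10⁻⁴) and is Multimodal, and the uniform grid survives the KS test.
Per-region outputs include the 1 m hypsometric curve, 15 m depth-band
areas, and SAR projections at z = 0.175/0.38/0.62.

The latitude analysis prints one row per coastline-hemisphere:

```
coastline hemisphere  pct_contractions  pct_expansions  coefficient_km2_per_deg      p_value  n_bins
DemoCoast          N               0.0        5.263158               996.123047 8.773003e-07  20
```

One of the 19 poleward steps (5.3%) is an expansion — exactly the built-in
width step ×2.5 at 20°N — and the trend coefficient (+996 km² per degree)
reflects the wider high-latitude shelf. A doubling of bin area corresponds
to a predicted +30.1% richness change at z = 0.38.

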