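# Methods

## The model in brief

The package treats European range expansion of the western corn rootworm
as a climate-envelope problem: temperature alone decides where the beetle
can be active and establish, a logistic curve decides how fast the
climatically suitable area fills in, and a latitude rule summarizes
country-level risk. Dispersal biology, trade pathways, overwintering egg
survival, soil properties and economics are deliberately outside the
envelope; the outputs are potential thermal limits, not full dispersal
dynamics.

## Synthetic climate generator

Real gridded observations (E-OBS-style) are emulated, not downloaded. The
monthly climatology is

T(lat, m) = a − λ·lat + A·cos(2π(m − 7)/12) + ε,

with the intercept *a* fixed so July at 45°N equals 22 °C, meridional
gradient λ = 0.7 °C per degree latitude, seasonal half-amplitude
A = 10 °C, and seeded cell noise ε ~ N(0, 0.5²). Annual grids add a linear
trend of 0.04 °C/yr **centred on 2005.5** (the midpoint of 1991–2020, so
the reference-period mean reproduces the climatology identically) plus a
smooth inter-annual anomaly surface (a 4-term seeded sinusoid basis scaled
to σ = 0.3 °C) so that coherent warm and cool regions exist by
construction. All stochastic components are driven by
`numpy.random.default_rng` seeded per (seed, year); identical seeds give
bit-identical rasters.

What the generator does **not** emulate: orography, continentality and
coastlines, skewed/extreme daily temperatures, spatially correlated noise
within a month, and the real historical sequence of warm years. Tests
passing on these grids therefore demonstrate the correctness of the
pipeline's logic and its monotonicity/identity properties — not skill on
real climate data.

The presence-history generator radiates first-detection years outward
from a point near Belgrade (20.5°E, 44.8°N; first European detection,
1992) at a configurable rate in degrees of arc per year, maturing statuses
through the standard vocabulary (absent → few occurrences → restricted →
widespread). It reproduces the qualitative radial pattern, not the
country-by-country historical record. Moldova is carried in the risk
fixture but excluded from presence generation, mirroring its exclusion
from the 2024 distribution analysis.

## Grids and I/O

All rasters are WGS84 lon/lat, cell-center registered, with half-open
cell ownership [edge, edge + res); the default window is 10°W–40°E,
35–70°N at 0.25° (analysis drivers use 1° for speed). Rasters are written
as Esri ASCII grids with `repr`-formatted floats so round-trips are
bit-exact; NaN maps to the NODATA value. GeoJSON layers are plain JSON
with shapely-built geometries. Geodesy uses the R = 6371 km sphere:
haversine distances, destination-point circles (96-gon), and a sinusoidal
equal-area projection for polygon areas.

## Warming schedule

ΔT(y) = 1.4 + (0.2/5)·(y − 2024) °C versus pre-industrial, matching every
printed 5-year value from 2024 (+1.4) to 2054 (+2.6) and extrapolating to
+3.4 °C at 2074 (needed by the third risk horizon, which has no printed
value). Warming applied to the present-day climatology is the *increment*
ΔT(y) − 1.4, since the climatology already represents current conditions.
The source text elsewhere mentions a 0.5 °C/5 yr step; the enumerated
5-yearly table is taken as authoritative, and the pipeline manifest
records the inconsistency. Annual mean temperature is the unweighted mean
of the 12 monthly means (a day-weighted variant is available via a flag);
GDD uses non-leap month lengths with no daily downscaling, consistent
with the monthly framing throughout.

## Suitability rules

Beetle: monthly mean ≥ 12.5 °C (activity) or ≥ 9 °C (establishment) for at
least two *calendar* months in a row within April–September; comparisons
are inclusive (≥). "Two consecutive months" is read as calendar months
because all inputs are monthly. A separate 15 °C warm-season mean is kept
only as the threshold of the presence/anomaly overlap diagnostic. The
species' own generation heat-sum is never quantified in the source and is
represented by this persistence proxy, not by an explicit degree-day
number.

Maize: suitable iff GDD(base 10) ≥ 1000 **and** some window month mean
≥ 10 °C **and** no window month maximum > 35 °C. The lower GDD bound is
the pass criterion because 1000–1400 is a hybrid-dependent range; air
temperature proxies soil temperature; when monthly maxima are not
simulated they default to mean + 6 °C (configurable) — only the
heat-stress clause consumes them.

Region fractions are cos(latitude)-weighted so cell areas are honest.

## Spread model

P(t) = k / (1 + ((k − p₀)/p₀)·e^(−rt)) with defaults p₀ = 0.40 at 2024,
k = 1, and r = 0.1117/yr obtained from the closed-form calibration
r = ln((P_T/(k−P_T)) / (p₀/(k−p₀)))/T with the single known endpoint
P(30) = 0.95. The spatial realization targets round(P(t)·n_suitable)
infested cells each year, adding suitable cells within the annual
dispersal radius of the infested set, nearest first, ties broken
lexicographically by (lat, lon) — fully deterministic. Infestation is
never revoked and infested ⊆ suitable holds at every step; if the
frontier cannot supply the target the shortfall is logged. The default
radius is 50 km/yr, chosen as a realistic unaided annual dispersal scale;
note it must be at least the grid spacing for the frontier to advance, so
1°-resolution runs use 200 km. Affected-age categories at a horizon use
5- and 15-year bands (newly ≤ 5 y, recently 5–15 y, longer > 15 y) — the
band widths are package defaults recorded in output metadata, as the
source names the categories without boundaries.

## Risk classification

The 29-country risk table is perfectly separable by centroid latitude at
each horizon, so the classifier is the simplest rule consistent with the
claimed geographic gradient: HR iff lat ≤ c_hr(h), MR iff
c_hr(h) < lat ≤ c_mr(h), LR otherwise, with cuts calibrated as midpoints
between adjacent classes' extreme latitudes (2034: 44.55/50.335; 2054:
46.90/51.64; 2074: 48.85/54.45 °N). Calibration fails loudly, naming the
violating countries, if classes overlap. Longitude is carried but unused.
Buffer layers draw geodesic circles of 300/200/100 km (HR/MR/LR) at 2034,
scaled ×1.5 at 2054 and ×2 at 2074 — radii are package defaults (the
source figures give none) and are written into layer properties. Three
asterisk typos in the printed table are read by their letter codes.

## Maize areas

Final area (k ha) = mean of the two source-year values in Mha, rounded
half-up to one decimal (decimal arithmetic, so 2.475 → 2.5 exactly),
× 1000. Bands partition [0, ∞): small < 500 ≤ moderate < 1000 ≤
large/medium ≤ 2000 < very large, with a merged three-band view
(weak/moderate/intensive) for coarse reporting. The continental projection
is exponential, a(y) = 6000·e^(ln(20/6)/30·(y−2024)) k ha, matching both
printed endpoints; an endpoint-matched linear variant is available. The
exponential is preferred because the published correlation series shows
accelerating expansion. Only Romania's area is printed in the source; the
other fixture values are synthetic, chosen to respect the published
intensity groupings.

## Problem sizes and numerical choices

Unit and property tests run at 1–2° resolution (35 × 50 cells and
smaller); the pipeline default is 0.25° (140 × 200), which completes in a
few seconds end-to-end. The brute-force persistence oracle is exercised on
10⁴ random month-vectors; logistic parameter recovery uses 100 seeded
noisy series (σ = 1 %-point, 31 annual points) refit with bounded
`scipy.optimize.curve_fit`. Ties in frontier growth and seeding are broken
lexicographically so all spatial outputs are reproducible byte-for-byte;
CSV/raster writers are deterministic. Degenerate inputs (empty year
ranges, empty presence sets, zero suitable cells, non-separable risk
tables, points off-grid) raise typed errors or return NaN sentinels as
documented per function.

## Known limitations

- Purely thermal envelope: no soil, moisture, photoperiod, host phenology,
  natural enemies, or human-assisted jumps (e.g. the anomalous 2002
  France-style detection), so realized spread will differ from the
  modelled frontier.
- The logistic is applied to the *suitable-area fraction*; the source does
  not state whether its curve tracks area, country counts or fraction.
- Latitude cuts are calibrated to one 29-row table; they are a summary of
  that table, not an independently validated classifier.
- The synthetic climate is idealized (see above); anomaly magnitudes in
  the P1–P6 maps reflect the imposed trend, not observed decadal patterns.
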