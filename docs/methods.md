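# Methods

This note records the statistical model behind `pseudosurvey`, the defaults
and why they were chosen, and what the synthetic validation does and does not
demonstrate.

## Resource model and sample frame

The target population is a continuous two-dimensional resource — all
estuarine water within a polygon set — represented as a `SampleFrame` in a
planar equal-area coordinate system with kilometre units (metre input is
rescaled on load). No reprojection machinery is bundled: callers supply
projected geometry, and identifiers that look geographic (EPSG:4326, WGS84)
are rejected because areas computed on longitude/latitude are meaningless.
Estimates are percentages of total frame area, so the equal-area requirement
is load-bearing, not cosmetic.

## Hexagonal harmonization grid

Secondary records are pooled into hexagonal cells sized from the frame area
and the intended number of assessment sites, so one cell corresponds to the
area one design site will represent. Two sizing conventions are implemented
because the two natural readings of "size determined by area" disagree
numerically:

* `area_exact` — cell area `= A/n`, hence spacing `s = sqrt(2(A/n)/√3)`;
* `paper_spacing` (default) — center spacing `s = 2·sqrt(A/n)`.

For the motivating 2705.90 km² study with n = 45, `area_exact` gives
≈ 8.3 km spacing while `paper_spacing` gives ≈ 15.5 km — matching the
roughly 16 km spacing and 134-cell clipped grid reported for that
application, which is why it is the default. The grid is anchored at the
lower-left corner of the frame's bounding box with flat-top orientation
(both anchor and orientation are conventions, exposed as arguments);
clipping retains every cell that intersects the frame, boundary touches
included. Cell ids derive from lattice (row, col) indices, and points on
shared edges are assigned to the lower (row, col) cell — an arbitrary but
deterministic tie-break. Hexagon vertices are built from exact half-spacing
offsets rather than trigonometric evaluation so shared edges coincide
bitwise; point-in-cell queries still carry a 1e-9·spacing tolerance for
boundary grazing.

## Record screening and standardization

The pipeline order is fixed: screen → replicates → non-detects → unit
conversion → outlier flags → freshwater screen → Winsorization → composite.
Each stage logs every exclusion with a machine-readable reason, and the whole
pipeline is deterministic given input and configuration.

* **Index window.** June–September; years configurable. Only surface
  measurements (depth ≤ 0.5 m) are kept.
* **Qualifiers.** User-supplied rules map codes to keep/exclude/review;
  unknown codes default to review (kept, logged) because secondary-data
  vocabularies cannot be assumed closed.
* **Replicates** (same site, datetime, parameter) are averaged
  arithmetically; mixed units within a replicate group are an error rather
  than a silent guess.
* **Non-detects** take the practical quantitation limit when reported,
  else the method detection limit; records with neither are excluded.
* **Salinity from specific conductance** uses the PSS-78 polynomial
  `S = Σ aₖ R^{k/2}`, `R = SC/53087 µS/cm`, assuming conductance is already
  temperature-compensated to 25 °C. The polynomial is unreliable below
  ~2 pss; negative outputs (and exactly zero conductance) clamp to 0.
* **Dissolved oxygen % saturation → mg/L** multiplies by the Benson–Krause
  equilibrium solubility (ln C* polynomial in inverse Kelvin with salinity
  correction, valid −2 to 40 °C), taking temperature and salinity from the
  same site visit; visits lacking either covariate are excluded rather than
  filled from climatology.
* **Outliers** beyond Q1 − 3·IQR / Q3 + 3·IQR within a parameter group are
  flagged for review, never auto-dropped: estuarine extremes are often real.
* **Freshwater visits** (salinity ≤ 0.05 pss, boundary inclusive) are
  flagged and by default dropped as outside the estuarine resource. The
  judgment step a human would apply (precipitation context, waterbody
  placement) is not automated.
* **99 % Winsorization** clamps each parameter group outside its
  [0.5th, 99.5th] percentile band — a symmetric two-tail reading, since the
  procedure targets extreme values in both tails. Quantiles use the linear
  interpolation convention throughout.

Compositing takes the geometric mean per hexagon-year for positive-support
parameters (concentrations, salinity) and the arithmetic mean for pH and
temperature, whose scales make a log-space mean inappropriate. Non-positive
values reaching a positive-support geometric mean are substituted with the
smaller of the MDL and half the minimum positive observed value (mirroring
the non-detect rule); if none exists the pipeline errors, naming the record.
The composite location is the arithmetic mean of the distinct contributing
site coordinates, kept per year to match the (hexagon, year) composite key.

## GRTS sampling

The sampler implements quadrant-recursive randomized addressing over the
frame's bounding square. Cells are subdivided until their frame-intersection
area (the selection mass) falls below `A/(4n)`, guaranteeing that the
systematic selection — step `A/n` along the randomized unit line with a
uniform random start — can hit each cell at most once; recursion is capped
at 11 levels. One point is placed uniformly in each selected cell∩frame by
rejection sampling. Reverse hierarchical ordering (base-4 digit reversal of
line position) makes every prefix of the ordered sample spatially balanced.
Because the cell tree geometry is seed-independent, a `GrtsEngine` is built
once per frame and reused across draws (~1 ms per draw on the test
estuaries), which is what makes 500-replicate coverage experiments cheap.
One seeded generator drives each draw; the seed is recorded in outputs.

Equal inclusion probability is verified by Monte-Carlo oracles (mean counts
in frame subregions, chi-square over an unequal partition), not assumed.

## Design reconciliation and scenarios

The GRTS draw and the data grid are constructed independently, so several
design points can share a data hexagon; only the first chronologically
generated (lowest order index) survives. Scenario assembly then joins
design points to composites for the requested years: multi-year scenarios
aggregate a hexagon's yearly composites by geometric mean across years
(arithmetic for pH/temperature), the cross-year analogue of the within-year
compositing operator. Design points without data are retained with
not-sampled markers — their weight is reported as the "Not sampled"
category — and weights use `n_effective` = all design rows, not just
data-bearing ones, so unsampled area is quantified instead of silently
renormalized away. Source selection happens *before* compositing (a pooled
composite cannot be unmixed), so per-source scenarios re-run harmonization
on the filtered records. Assessments with fewer than 30 sites warn rather
than fail; 30 spatially balanced sites is the design minimum for 90 %
confidence in variance estimates.

## Estimation and variance

All estimators are Horvitz–Thompson with equal weights `w = A/n`:
percent-of-area estimates are weighted indicator shares and means are
weighted ratios over sampled sites. Category rules: quartile schemes assign
Low strictly below the first break and High strictly above the second
(boundary values are Moderate); criteria schemes assign Above only on strict
exceedance. Missing is always its own category.

Variance uses the local-mean neighbourhood estimator for continuous-resource
designs: each site's estimator contribution `zᵢ = wᵢ(yᵢ − μ̂)/Σw` is
contrasted with a smoothed mean over its 4 nearest sites (self-inclusive).
Smoothing weights start uniform at 1/4 over each neighbourhood and are
row/column-normalized by iterative proportional fitting (≤100 iterations,
1e-10 tolerance). Each neighbourhood's weighted squared-deviation sum is
divided by `1 − Σⱼ wᵢⱼ²` — the weighted-variance analogue of Bessel's
correction — because deviations are measured from a mean estimated inside
the same four-site neighbourhood and would otherwise be shrunk by exactly
that factor. With the correction, the estimator reproduces the SRS variance
on independent uniformly scattered data (ratio ≈ 1.0 in Monte-Carlo) and is
mildly conservative under spatially balanced designs on smooth surfaces,
which is the safe direction for condition reporting. Fewer than four sites,
or fewer than four distinct locations, fall back to the with-replacement SRS
variance with a warning. Intervals are normal-approximation (z = 1.96 for
95 %, 1.645 for 90 %), clipped to [0, 100] on the percent scale. Change
analysis treats the two periods as independent surveys (no covariance term),
so `var(Δ) = var_A + var_B` and the 95 % half-width is
`sqrt(moe_A² + moe_B²)` exactly.

## Balance and representativeness diagnostics

Spatial balance clips the Voronoi tessellation of a site set to the frame
and scores the normalized cell totals `vᵢ = n·areaᵢ/A` (1 under perfect
balance): Pielou evenness `1 − H/ln n` (entropy H of area shares; 0 best)
or `rmse = sqrt(mean((vᵢ−1)²))`. Disjoint frame parts are implicitly
assigned to the nearest site by the Voronoi partition itself. The published
RMSE variant is ambiguous about what it is computed on; the Voronoi reading
is implemented here and the ambiguity noted. The null-mean simulation
bootstraps (with replacement, full size by default; fraction and replacement
are configurable since the subset rule is not standardized) the reduced
dataset's mean against the 95 % interval of the observed raw mean and
reports the inside fraction as a p-value — high values mean the reduced
data reproduce the observed centre.

## Synthetic study conditions

`make_estuary` unions elliptical bay lobes on a nearshore lagoon strip with
narrow buffered-line river arms; the gradient coordinate runs 0 (river
heads) to 1 (marine edge) linearly in the cross-shore direction. The
default surfaces emulate summer field magnitudes: salinity rising seaward
(≈0–30 pss), chlorophyll and nutrients falling seaward, temperature ≈29–30
°C with monthly offsets, and lognormal noise for concentration-like
parameters (normal for temperature and pH) so skew matches real summaries
where means far exceed medians (enterococci most extremely). The targeted
source scatters sites around a few cluster centres with 1–10 visits per
site and per-visit parameter dropout; the probabilistic source is a GRTS
draw visited once with full parameter coverage. Detection-limit censoring,
alternate reporting units (conductance, % saturation) and qualifier codes
are injected at configurable rates to exercise every screening rule.

Ground truth integrates the *noise-free* median surface over a stratified
jittered point grid (one deterministic jittered point per 0.25–0.5 km
pixel; jitter removes the quantization bias an aligned lattice shows when a
category boundary parallels a grid row). Estimator validation therefore
tests design-based properties — equal inclusion, unbiased shares, interval
coverage — under the design-based premise that the measured value is a
fixed property of location. What passing does **not** show: robustness to
measurement noise, temporal drift within scenarios, spatially correlated
reporting artifacts between programs, or the open-water homogeneity of real
estuaries; the synthetic gradients are smoother than nature.

## Problem sizes

Validation experiments use 500 replicates for coverage (n = 30) and
unbiasedness (n = 45) and 100 draws per arm for balance comparisons —
enough for ~±1–3 percentage-point Monte-Carlo resolution, which matches the
granularity of the claims being checked. The truth integration uses a
0.25 km grid (~10⁴ points on the ~540 km² test estuary), where refinement
changes results by well under 1 %.

## Known limitations

* No CRS transformation: inputs must share one equal-area planar CRS.
* Shapefile input is not read; frames are GeoJSON (or constructed in code).
* The exact reported 45→36 site reconciliation of the motivating study is a
  property of one random realization and one specific grid; only its
  statistical shape (dedup ratio, balance, coverage) is reproducible.
* Unstratified equal-probability designs only; no oversample/replacement
  panels, unequal-probability or stratified variants.
* The local-mean smoothing weight construction follows the neighbourhood
  recipe in the survey literature but is pinned by this package's own
  regression oracle, not by an external implementation.
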