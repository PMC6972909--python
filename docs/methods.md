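# Methods

This note documents the statistical model, the synthetic-data design, the
numerical conventions, and the limits of what the shipped experiments
demonstrate.

## Statistical model

The quantity of interest at each grid pixel is the second-order partial
correlation between monthly NDVI anomalies and windowed precipitation
anomalies, controlling temperature and radiation anomalies. The
coefficient is computed by the classical recursion over Pearson
correlations (first order, then second order) rather than by matrix
inversion; tests verify the recursion against the regression-residual
construction and against an independent implementation to 1e-10.
Significance is a two-sided Student t-test with df = n − 2 − (number of
controls). With 34 analysis years and two controls, df = 30 and the
critical |r| at α = 0.05 is ≈ 0.349 (0.554 at α = 0.001).

Missing data are handled listwise on the full (NDVI, precipitation,
temperature, radiation) tuple: a year is dropped from all four series if
any one is missing, so every pairwise correlation inside the recursion
shares one sample. Degenerate cases — constant series, perfectly
collinear controls — propagate as missing cells, never as zeros.

No multiple-testing correction is applied across the 168 per-pixel
analyses or across pixels. That choice is deliberate: the family-wise
"any of 24 significant" rate under the null is therefore well above the
per-test α (≈ 0.77 on the shipped null experiment), and maps masked by
any-significance must be read accordingly.

### Temporal design

Lags 0–3 months × cumulation periods 1–6 months, indexed lag-major
(j = 6·lag + cumper, j = 1…24). The window for (l, c) covers months
l … l+c−1 before the NDVI month, inclusive of the current month when
l = 0; the deepest window (l = 3, c = 6) reaches 8 months back, which is
why anomaly records start one year before the first analysis year.
Control variables are accumulated over the same window as precipitation
(`controls_window="matched"`); fixing the controls at lag 0 with the same
cumulation period is available as `"lag0"`. Matching keeps the
partialling symmetric in time; the lag-0 alternative is provided because
either reading of "anomaly composites over 1–6 months" is defensible.

Maxima over months (r_j) and over combinations (r_max) are maxima of the
*signed* coefficient; a pixel dominated by negative correlation shows a
negative r_max rather than |r|. The p-value attached to r_j is the one
from its maximising month. Ties in the argmax resolve to the smallest
lag, then the smallest cumulation period (the lag-major scan order makes
the first occurrence the winner).

### Seasons

Growing season April–October, split into spring (Apr–May), summer
(Jun–Aug) and autumn (Sep–Oct). The non-growing "winter" season is
defined here as November–March, labelled by the year of its Jan–Mar part,
so the four seasons partition the calendar year and "previous season"
arithmetic is well defined (spring's previous season is winter, reaching
Nov–Dec of the prior year). Winter's month set is configurable; results
for the previous-season mode of spring depend on it. Seasonal NDVI
averages its months' anomalies; seasonal precipitation sums them (an
index versus a physical flux); controls average over the precipitation
window. For fixed windows, aggregate-then-anomalise and
anomalise-then-aggregate are identical for means and sums, so the engine
aggregates monthly anomalies.

### Indices

* MAP: mean over years of 12-month totals (full calendar years required).
* FPD: annual wet-day count over days in the year, leap-aware, averaged
  over years. Wet-day counts are taken as given; the threshold defining a
  "wet day" is upstream of this package.
* PCI: computed per year and averaged over years (the alternative — PCI
  of the mean climatology — is available via `per_year=False`; it is
  systematically lower because interannual noise adds concentration).
  Uniform rainfall gives 100/12 ≈ 8.33; total concentration gives 100.
* Angstrom coefficients default to a_s = 0.25, b_s = 0.50 (the standard
  FAO-56 values), configurable.
* Threshold ranges for the high-response regime default to 150–500 mm
  MAP, 0.075–0.275 FPD, 19–23 PCI, treated as closed intervals.

### Attribution

Binned averages use uniform bins anchored at 0, left-closed/right-open;
default widths 50 mm (MAP), 0.025 (FPD), 1 (PCI), 1000 m (elevation),
1 (CTI), 0.1 g/cm³ (SBD), 50 mm (PAWC); bins and zones with fewer than
10 members are excluded; error bars are ± SD/2. Zone quantiles
(5/25/50/75/95) interpolate linearly between order statistics.
Ecological zones are the intersection of one land-cover class with one
ecoregion; built-up pixels are excluded by the QC mask. The zone
box-plot's reference lines are the critical |r| at α = 0.05 and 0.001 for
the analysis sample size.

## Synthetic data

The generator emulates the *shape* of a 0.5°-style monthly archive,
1981–2015 (the leading year exists to feed lagged windows):

* **Precipitation**: gamma-distributed around a summer-peaked monthly-mean
  cycle (16–70 mm; ≈ 364 mm/yr at scale 1) with dispersion
  var = d·mean² and d = 1 by default. Smooth per-pixel regime fields
  multiply the means (0.4–1.6, so MAP spans ≈ 150–580 mm), the dispersion
  (0.7–1.3, per-year PCI ≈ 15–23) and the wet-day fractions (0.5–1.5,
  FPD ≈ 0.08–0.23), giving the domain the index gradients that the
  threshold-selection and binned-attribution analyses need.

  The seasonal concentration of the mean cycle is deliberately moderate.
  With a sharply peaked cycle the dry months contribute negligible anomaly
  variance, adjacent cumulation windows become near-collinear, and the
  embedded lag/cumulation truth is statistically unidentifiable at 34
  samples — defeating the generator's purpose. Interannual concentration
  (the per-year PCI level) is therefore produced by the gamma dispersion,
  which scales all monthly variances proportionally and leaves the window
  geometry intact.
* **Temperature / radiation**: sinusoidal cycles (July / late-June peaks)
  plus Gaussian noise.
* **Wet days**: rounded days-in-month × monthly wet fraction plus Gaussian
  jitter, clipped to [0, days-in-month]. **Sunshine**: fraction of a 12-h
  day, clipped.
* **NDVI**: a grassland-like baseline cycle plus the anomaly
  β·z(P_acc) + γ·z(T) + δ·z(R) + ε, where P_acc is the precipitation
  anomaly summed over the pixel's true (l\*, c\*) window, z(·)
  standardises per calendar month over the generation period (so β is in
  NDVI units per SD of accumulated anomaly and comparable across pixels),
  and ε ~ N(0, σ²). Defaults: β = 0.08, γ = δ = 0.02, σ = 0.024
  (= 0.3 β). (l\*, c\*) are drawn uniformly over the full design. Pixels
  are flagged *recoverable* when |β| ≥ 2σ.
* **Landscape**: land-cover classes drawn i.i.d. from configured
  proportions, ecoregions as longitude bands, ecological zones as their
  intersection; smooth random fields for elevation/CTI/SBD/PAWC;
  Bernoulli built-up flags (2 %).

All randomness flows from one seed through named substreams, so identical
configurations are bit-reproducible.

**What the synthetic experiments do and do not show.** They verify the
machinery: the engine finds exactly the structure that was embedded
(≈ 90 % exact recovery at σ = 0.3β; lag within ±1 month for ≈ 99 % at
σ = β), the tests are calibrated under the null, and the attribution
statistics match their definitions. They do not emulate spatial
autocorrelation of weather, monsoon dynamics, snow processes, phenology,
sensor artefacts, or NDVI saturation — so passing here says the pipeline
is correct, not that any particular real-world domain has recoverable
structure of this strength. At σ = |β| the QC rule (NDVI ≤ 0 in the
growing season marks a pixel contaminated) removes a substantial fraction
of pixels, since large noise excursions cross zero from a low baseline;
statistics at that noise level describe the surviving pixels.

## Numerical choices

* Anomaly base period 1982–2015; months of pre-base years are anomalised
  against the base-period climatology.
* Area-weighted regional means weight by cos(latitude), renormalised over
  valid pixels at each time step.
* NDVI 8-km→0.5° style aggregation defaults to block means (missing cells
  ignored; a coarse cell is missing only if all fine cells are).
* The abnormal-value QC rule defaults to NDVI ≤ 0 in any growing-season
  month; configurable predicate.
* Correlations are clipped into [−1, 1] against floating-point drift;
  |control correlation| ≥ 1 − 1e−12 is treated as degenerate.
* NetCDF files are NetCDF3 classic (xarray/scipy backend) with an explicit
  `_FillValue`; internally missing cells are NaN.
* Experiment sizes in the shipped verification: 1000 random quadruplets
  for the oracle check, a 50 × 50 null grid, 30 × 30 recovery grids, a
  20 × 20 end-to-end default — sizes chosen so the whole verification runs
  in seconds while Monte-Carlo errors stay small relative to the margins
  being checked.

## Known limitations

* No effective-sample-size correction for serial correlation in the
  year-indexed series, and no field significance across pixels.
* The maximum over 168 dependent analyses inflates r_max under the null;
  r_max maps are meaningful only jointly with the significance mask.
* GeoTIFF ingestion is not implemented; NetCDF is the interchange format.
* Sub-monthly structure exists only as the optional paired composites used
  to exercise maximum-value compositing.
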