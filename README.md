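# vegresponse

Spatiotemporal analysis of how vegetation greenness responds to
precipitation anomalies on monthly climate grids — for ecohydrologists and
vegetation–climate researchers who want the full lag/accumulation
partial-correlation workflow (plus its attribution analyses) as a tested,
reusable library rather than a one-off script stack.

## The method

Vegetation activity is tracked by NDVI (Normalized Difference Vegetation
Index) anomalies; the climate drivers are monthly precipitation,
temperature and solar-radiation anomalies, each a deviation from the
per-calendar-month climatology over a base period. Because temperature and
radiation co-vary with precipitation, the association of interest is the
**second-order partial correlation** between NDVI and precipitation
anomalies with the other two drivers held fixed:

    r_12.3  = (r_12 − r_13 r_23) / √((1 − r_13²)(1 − r_23²))
    r_12.34 = (r_12.3 − r_14.3 r_24.3) / √((1 − r_14.3²)(1 − r_24.3²))

where 1 = NDVI, 2 = precipitation, 3 = temperature, 4 = radiation.
Significance is a two-sided t-test with t = r√(df/(1−r²)), df = n − 2 − 2.

Vegetation integrates water supply over time, so the precipitation signal
is scanned over a **4 × 6 design**: time lags of 0–3 months crossed with
cumulation periods of 1–6 months. Combination j (lag l, cumulation c) sums
precipitation anomalies over the c consecutive months ending l months
before the NDVI month. For each pixel and each growing-season month
i = April…October this gives

    r_{i,j} = parcor(NDVIano_i, PRano_{i,j} | TMPano, RADano)   (7 × 24 = 168 analyses)
    r_j     = max_{4≤i≤10} r_{i,j}
    r_max   = max_{1≤j≤24} r_j

`r_max` maps where vegetation is precipitation-controlled; the argmax
(best lag, best cumulation) maps *how fast* and *over what memory* it
responds. Three precipitation-regime indices attribute the spatial
pattern: MAP (mean annual precipitation, mm/yr), FPD (fraction of
precipitation days) and PCI (precipitation concentration index,
100·Σp_i²/(Σp_i)² over the 12 monthly totals). Binned averages of r_max
along these and along terrain/soil covariates, box statistics by
ecological zone (land-cover × ecoregion intersection) and seasonal
correlation modes (same-season, previous-season and two-season windows)
complete the workflow. The Angstrom formula R_s = (a_s + b_s·n/N)·R_a
estimates solar radiation from sunshine hours where radiation is not
observed.

Everything runs end-to-end on synthetic gridded data with a *known*
embedded response — each pixel is assigned a true (lag, cumulation, effect
size) — so the whole chain is verifiable by parameter recovery.

## Worked example

```python
from vegresponse import (SyntheticConfig, generate_dataset, monthly_anomalies,
                         qc_mask, TemporalResponseModel)

cfg = SyntheticConfig(n_lat=20, n_lon=20, seed=7)      # 1981–2015 monthly grids
data = generate_dataset(cfg)
mask = qc_mask(data["ndvi"].select_years(1982, 2015), builtup=data["builtup"])
anos = {k: monthly_anomalies(data[k], (1982, 2015))
        for k in ("ndvi", "precip", "temp", "radiation")}
res = TemporalResponseModel(anos["ndvi"], anos["precip"], anos["temp"],
                            anos["radiation"], mask=mask).fit()
print(res.summary())
```

```
Temporal response of NDVI to precipitation anomalies
====================================================
grid: 20 x 20 pixels, years 1982-2015
design: 24 (lag, cumper) combinations x 7 months = 168 analyses/pixel
alpha = 0.05, controls window = matched
pixels with any significant correlation: 100.0%
median r_max over significant pixels: 0.941

best-lag shares (cumper = 1), % of significant pixels:
lag
0    22.8
1    20.5
2    27.9
3    28.9

best-cumulation shares (lag = 0), % of significant pixels:
cumper
1     6.1
2     7.9
3    11.8
4    16.6
5    18.9
6    38.6
```

Reading it: every valid pixel carries a significant precipitation signal
(the generator embeds one, with noise at 30 % of the effect size); the
median peak partial correlation is 0.94. Because each pixel's true lag was
drawn uniformly from 0–3 months, the best-lag shares are near-uniform;
the best-cumulation shares tilt toward long windows because a long-memory
pixel is still fairly well approximated by shorter overlapping windows,
while the reverse mis-fit costs more. Comparing the argmax maps against
the generator's truth table recovers the embedded (lag, cumulation)
exactly for 91.8 % of pixels here.

The same workflow is scriptable from the shell:

```sh
vegresponse run-all --seed 7 --out results/
vegresponse temporal-response --ndvi ndvi.nc --precip pre.nc \
    --temp tmp.nc --rad rad.nc --alpha 0.05 --out temporal.nc
```

`run-all` executes generation → QC/anomalies → indices →
temporal/seasonal response → attribution and writes a manifest of SHA-256
hashes; the same config and seed reproduce it byte for byte.

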