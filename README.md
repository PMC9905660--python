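# climtrack

Climate-tracking analysis of repeated Arctic shorebird plot surveys.

Arctic-breeding shorebirds are expected to shift their breeding ranges
poleward as the tundra warms. `climtrack` tests for that signal in repeated
plot-survey data: given two survey eras of per-plot bird counts, it computes
per-species **occupancy change**, summarises each species' climate envelope
as a **species temperature index** (STI — the long-term mean June
temperature over its breeding range, a zonal statistic of a climate raster
clipped to a range polygon), and regresses percent occupancy change on STI.
A positive slope means warmer-breeding species are moving in while
colder-breeding species are moving out — the fingerprint of a northward
community shift. It is aimed at quantitative ecologists working with
PRISM-style Arctic plot surveys (16-ha plots, two regions, upland/lowland
habitats) or any comparable repeated-survey design.

The package provides:

* `survey` — ingest long-format survey CSVs; occupancy, species richness
  (species/plot) and density (birds/km²) per plot and per era.
* `climate` — single-band GeoTIFF or ESRI ASCII grid rasters, GeoJSON range
  polygons, cell-center zonal statistics with optional cos(latitude)
  area weighting.
* `glm` — community models fitted from first principles by IRLS:
  binomial-logit occupancy and NB2 negative-binomial (variance μ + μ²/θ,
  log link, profile-ML θ) richness and density, with additive era + region +
  habitat effects and Wald z-tests.
* `change` — percent change in occupied-plot counts
  (100·(k_late − k_early)/k_early, undefined when k_early = 0) and the
  `ClimateTrackingRegression` OLS model of change on STI.
* `simulate` — a generative range-shift model: a linear meridional
  temperature gradient, latitudinal-band ranges centred on each species'
  STI isotherm, centre-peaked occupancy, and a poleward displacement of
  ΔT/|gradient| degrees under warming ΔT. Used for end-to-end validation
  (type-I error and power of the STI regression) with no external data.
* a `climtrack` CLI (`simulate / occupancy / sti / glm / regress / full`).

## Worked example

The package ships the published per-species summary for the Foxe Basin and
Rasmussen Lowlands surveys (12 species, 64 plots per era) as a reference
fixture. Occupied-plot counts are reconstructed from the printed
percentages (`round(pct × 64 / 100)`), joined with each species' STI, and
the headline regression fitted over the 10 species with a defined change:

```python
from climtrack import (ClimateTrackingRegression, SpeciesOccupancy,
                       SpeciesTemperatureIndex, assemble_change_table,
                       format_change_table, load_reference_table,
                       reconstruct_occupied_counts)

ref = load_reference_table()
occs, stis = [], []
for _, row in ref.iterrows():
    occs.append(SpeciesOccupancy(row.code, "early",
                int(reconstruct_occupied_counts(row.occ_early_pct)), 64))
    occs.append(SpeciesOccupancy(row.code, "late",
                int(reconstruct_occupied_counts(row.occ_late_pct)), 64))
    stis.append(SpeciesTemperatureIndex(row.code, row.sti_degc, 1, False))

table = assemble_change_table(occs, stis)
print(format_change_table(table).to_string(index=False))
print(ClimateTrackingRegression.from_change_table(table).fit().summary())
```

prints

```
species  sti_degc  occ_early_pct  occ_late_pct pct_change  included
   REKN      -1.3         0.0000        1.5625        Inf     False
   RUTU      -0.2         7.8125       12.5000         60      True
   BASA       1.2         6.2500        0.0000       -100      True
   BBPL       1.2        10.9375        7.8125        -29      True
   BBSA       1.5         1.5625        0.0000       -100      True
   WRSA       1.6        43.7500       46.8750          7      True
   REPH       2.2        64.0625       50.0000        -22      True
   PESA       3.3        23.4375       20.3125        -13      True
   DUNL       3.8         9.3750       20.3125        117      True
   AMGP       5.0         6.2500       18.7500        200      True
   SESA       5.1         6.2500       25.0000        300      True
   STSA       5.3         0.0000        6.2500        Inf     False

OLS: pct_change ~ STI   n = 10
  intercept  -94.2391
  slope       55.1557  (SE 17.2246)
  t = 3.2021  p = 0.01257  R2 = 0.5617  adj R2 = 0.5069
```

Reading the output: Red Knot (REKN) and Stilt Sandpiper (STSA) — the
coldest- and warmest-breeding species — were never detected in the early
era, so their change is undefined (`Inf`) and they are excluded from the
fit. Among the rest, percent change rises steeply with STI: each extra
degree of breeding-range temperature is associated with ≈55 percentage
points more occupancy gain (p ≈ 0.013, adjusted R² ≈ 0.51) — the
warmer-breeding third of the community is gaining ground in these regions
while the colder-breeding species retreat.

The same analysis from the shell:

```sh
climtrack regress --sti-mode load_table --out results/
climtrack simulate --out world/ --seed 7          # synthetic world
climtrack full --surveys world/surveys.csv \
    --raster world/climate_early.tif --ranges world/ranges_early.geojson \
    --out results_synth/
```

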