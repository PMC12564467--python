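# dvvrisk

Climate-envelope spatial risk analysis for the **western corn rootworm**
(*Diabrotica virgifera virgifera* Le Conte), an invasive chrysomelid beetle
whose larvae feed on maize roots. Since its first European detection near
Belgrade in 1992 the species has expanded across the continent, and
continued warming is expected to open progressively higher latitudes to
both the beetle and its host crop. This package implements the full
analysis chain as a tested Python library with numbered analysis drivers,
for pest-risk modellers and plant-health analysts who want a transparent,
reproducible version of the centroid/threshold approach.

## What it computes

1. **Synthetic climate grids** (`dvvrisk.synthetic`) — monthly mean
   temperatures on a lon/lat grid with E-OBS-like structure: latitude-
   dominated climatology, July-peaked seasonal cycle, a 0.04 °C/yr trend
   centred on the 1991–2020 reference, smooth inter-annual anomaly fields,
   seeded noise. All downstream stages run with no downloads.
2. **Warming schedule and anomalies** (`dvvrisk.climate`) — the anchored
   linear schedule ΔT(y) = 1.4 + 0.04·(y − 2024) °C (so +2.6 °C at 2054,
   +3.4 °C extrapolated at 2074); DAT rasters (period mean minus 1991–2020
   reference mean) for the six cumulative periods P1–P6; warm-season
   (April–September) means; growing degree days
   GDD = Σₘ max(0, Tₘ − T_base)·daysₘ.
3. **Suitability** (`dvvrisk.suitability`) — a cell is suitable for beetle
   *activity* (*establishment*) when its monthly mean is ≥ 12.5 °C (≥ 9 °C)
   for ≥ 2 consecutive growing-season months; maize needs ≥ 1000 GDD
   (base 10 °C), a germination month ≥ 10 °C, and no month above 35 °C.
4. **Spread** (`dvvrisk.spread`) — the infested fraction of suitable area
   follows P(t) = k / (1 + ((k − p₀)/p₀)·e^(−rt)) with p₀ = 0.40 at 2024
   and r = 0.1117/yr (calibrated so P(30) = 0.95), realized spatially by
   deterministic nearest-first frontier growth within an annual dispersal
   radius.
5. **Risk classification** (`dvvrisk.risk`) — the published 29-country
   risk table (LR/MR/HR at 2034/2054/2074) is perfectly latitude-separable;
   midpoint-calibrated latitude cuts reproduce all 87 cells, and geodesic
   buffer circles around at-risk centroids give the map layers.
6. **Maize** (`dvvrisk.maize`) — the two-year-average area formula
   (2.5 Mha → 2500 k ha), four cultivation bands, and the exponential
   continental expansion curve 6 000 k ha (2024) → 20 Mha (2054).

## Worked example

```python
from dvvrisk import (LogisticParams, WarmingSchedule, logistic_fraction,
                     project_area, load_centroid_fixture,
                     calibrate_latitude_cuts, risk_table)

print(WarmingSchedule().delta(2054))            # 2.6
print(100 * logistic_fraction(30, LogisticParams()))  # 95.00520301900025
print(project_area(2054) / 1000)                # 20.000000000000004

fixture = load_centroid_fixture()
cuts = calibrate_latitude_cuts(fixture)
_, agreement = risk_table(fixture, cuts)
print(agreement)   # {2034: (29, 29), 2054: (29, 29), 2074: (29, 29)}
```

The numbers read: +2.6 °C of warming at the 2054 horizon; 95% of
climatically suitable area infested 30 years after 2024; a projected
20 million ha of continental maize at 2054; and the latitude-cut
classifier reproducing every row of the 29-country risk table at all
three horizons.

## Analysis drivers

The `analysis/` scripts run the narrative end-to-end at 1° resolution and
write tables/rasters under `results/`:

```bash
python analysis/01_synthesize_climate.py
python analysis/02_temperature_anomalies.py
python analysis/03_suitability_masks.py
python analysis/04_spread_simulation.py
python analysis/05_maize_areas.py
python analysis/06_risk_classification.py
python analysis/07_joint_series.py
```

A `dvv` command exposes the same stages (`dvv run`, `dvv risk table`,
`dvv maize project 2044`, ...), and `dvvrisk.pipeline.run_pipeline` chains
everything from a flat key=value config into one artifact bundle
(Esri ASCII rasters, CSV tables, GeoJSON layers, and a manifest recording
every parameter and seed).

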