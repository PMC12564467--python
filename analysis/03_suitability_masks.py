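#!/usr/bin/env python
"""Thermal suitability for the beetle and for maize at the three horizons.

Applies the warming schedule (extra warming over the 2024 baseline) to the
reference climatology and classifies cells with the 12.5 °C activity /
9 °C establishment persistence rule and the maize GDD-germination-heat
rule.  Reports how far the suitable frontier moves poleward.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from dvvrisk.climate import WarmingSchedule
from dvvrisk.grids import GridSpec, write_ascii_grid
from dvvrisk.suitability import maize_suitability_mask, pest_suitability_mask
from dvvrisk.synthetic import ClimatologyParams, generate_climatology

OUT = Path("results/03_suitability")
GRID = GridSpec(resolution=1.0)
HORIZONS = (2024, 2034, 2054, 2074)


def frontier_lat(mask: np.ndarray) -> float:
    rows = mask.any(axis=1)
    return float(GRID.lats()[rows].max()) if rows.any() else float("nan")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    clim = generate_climatology(GRID, ClimatologyParams())
    schedule = WarmingSchedule()

    rows = []
    for year in HORIZONS:
        warmed = clim.shifted(schedule.delta_vs_present(year))
        activity, establishment = pest_suitability_mask(warmed)
        maize = maize_suitability_mask(warmed)
        for name, m in (("pest_activity", activity), ("pest_establishment", establishment), ("maize", maize)):
            write_ascii_grid(OUT / f"{name}_{year}.asc", m.mask.astype(float), GRID)
        rows.append(
            {
                "year": year,
                "delta_vs_2024_c": schedule.delta_vs_present(year),
                "activity_cells": activity.n_suitable,
                "establishment_cells": establishment.n_suitable,
                "maize_cells": maize.n_suitable,
                "activity_frontier_lat": frontier_lat(activity.mask),
                "maize_frontier_lat": frontier_lat(maize.mask),
            }
        )
    table = pd.DataFrame(rows)
    table.to_csv(OUT / "suitability_summary.csv", index=False)
    print(table.to_string(index=False))
    shift = table["activity_frontier_lat"].iloc[-1] - table["activity_frontier_lat"].iloc[0]
    print(f"\nbeetle-activity frontier shifts {shift:+.1f} deg latitude from 2024 to 2074")
    print(f"outputs -> {OUT}")


if __name__ == "__main__":
    main()
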