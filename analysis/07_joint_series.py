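#!/usr/bin/env python
"""Joint 2024–2054 series: warming ΔT, maize area, and beetle spread.

Combines the warming schedule, the maize expansion curve, and the realized
spread series from the cellular simulation into one aligned annual table —
the analysis' central correlation exhibit.
"""

from pathlib import Path

import pandas as pd

from dvvrisk.climate import WarmingSchedule
from dvvrisk.maize import MaizeGrowthCurve
from dvvrisk.risk import joint_series

OUT = Path("results/07_joint")
SPREAD_CSV = Path("results/04_spread/spread_series.csv")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    if not SPREAD_CSV.exists():
        raise SystemExit("run analysis/04_spread_simulation.py first")
    spread = pd.read_csv(SPREAD_CSV)
    table = joint_series(WarmingSchedule(), MaizeGrowthCurve(), spread)
    table.to_csv(OUT / "joint_series.csv", index=False)
    show = table[table["year"].isin((2024, 2034, 2044, 2054))]
    print(show.to_string(index=False, float_format=lambda v: f"{v:,.1f}"))
    first, last = table.iloc[0], table.iloc[-1]
    print(f"\n2024->2054: dT {first['delta_t_c']:.1f}->{last['delta_t_c']:.1f} C, "
          f"maize {first['maize_area_kha'] / 1000:.0f}->{last['maize_area_kha'] / 1000:.0f} Mha, "
          f"spread {first['spread_pct']:.0f}->{last['spread_pct']:.0f}%")
    print(f"outputs -> {OUT}")


if __name__ == "__main__":
    main()
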