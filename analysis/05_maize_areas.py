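#!/usr/bin/env python
"""Per-country maize areas, cultivation bands, and the continental projection.

Applies the two-year-average estimation formula and the four-band area
classification to the packaged country fixture, then evaluates the
exponential expansion curve (6,000 k ha at 2024 → 20 Mha at 2054).
"""

from pathlib import Path

import pandas as pd

from dvvrisk.maize import area_table, project_area
from dvvrisk.synthetic import load_maize_area_fixture

OUT = Path("results/05_maize")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    table = area_table(load_maize_area_fixture())
    table.to_csv(OUT / "maize_areas.csv", index=False)
    print("band counts:")
    print(table["band"].value_counts().to_string())
    print(f"\nRomania worked example: {table.set_index('country').loc['Romania', 'final_area_kha']:.0f} k ha")

    proj = pd.DataFrame(
        {"year": list(range(2024, 2055, 5)),
         "area_kha": [project_area(y) for y in range(2024, 2055, 5)]}
    )
    proj.to_csv(OUT / "maize_projection.csv", index=False)
    print("\ncontinental projection (k ha):")
    print(proj.to_string(index=False, float_format=lambda v: f"{v:,.0f}"))
    print(f"\n2054 rounds to {round(project_area(2054) / 1000)} million ha")
    print(f"outputs -> {OUT}")


if __name__ == "__main__":
    main()
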