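#!/usr/bin/env python
"""Country-level risk classification and buffer-zone layers.

Calibrates the per-horizon latitude cuts from the 29-country centroid
fixture (midpoints between adjacent risk classes), verifies the table is
reproduced, and writes geodesic buffer circles for the at-risk countries.
"""

import json
from pathlib import Path

from dvvrisk.risk import HORIZONS, buffer_zones, buffer_zones_geojson, calibrate_latitude_cuts, risk_table
from dvvrisk.synthetic import load_centroid_fixture

OUT = Path("results/06_risk")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    fixture = load_centroid_fixture()
    cuts = calibrate_latitude_cuts(fixture)
    table, agreement = risk_table(fixture, cuts)
    table.to_csv(OUT / "risk_table.csv", index=False)

    print("calibrated latitude cuts (HR<=, MR<=):")
    for h in HORIZONS:
        c_hr, c_mr = cuts.at(h)
        ok, n = agreement[h]
        print(f"  {h}: {c_hr:.3f} N / {c_mr:.3f} N   agreement {ok}/{n}")

    for h in HORIZONS:
        zones = buffer_zones(fixture, h)
        (OUT / f"buffer_zones_{h}.geojson").write_text(
            json.dumps(buffer_zones_geojson(zones), indent=1)
        )
        print(f"  {h}: {len(zones)} HR/MR buffer zones")
    print(f"outputs -> {OUT}")


if __name__ == "__main__":
    main()
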