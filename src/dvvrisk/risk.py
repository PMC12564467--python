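"""Centroid-based country risk classification and buffer-zone layers.

The published 29-country risk table assigns each country LR/MR/HR at the
2034/2054/2074 horizons.  The classes turn out to be perfectly separable by
centroid latitude at every horizon, so the classifier is a latitude-threshold
rule whose two cut points per horizon are calibrated as midpoints between
the adjacent classes' extreme latitudes.  Longitude is carried but unused by
the default rule.
"""

from __future__ import annotations

import dataclasses
import enum
from typing import Callable, Iterable, Mapping

import numpy as np
import pandas as pd

from .climate import WarmingSchedule
from .geo import geodesic_circle
from .maize import MaizeGrowthCurve, project_area

__all__ = [
    "RiskClass",
    "LatitudeCuts",
    "BufferZone",
    "CalibrationError",
    "HORIZONS",
    "calibrate_latitude_cuts",
    "classify_country",
    "risk_table",
    "default_radius_rule",
    "buffer_zones",
    "buffer_zones_geojson",
    "joint_series",
]

HORIZONS = (2034, 2054, 2074)


class CalibrationError(ValueError):
    """Risk classes are not latitude-separable; names the violators."""


class RiskClass(enum.IntEnum):
    """Ordered risk classes, low to high."""

    LR = 0
    MR = 1
    HR = 2

    @classmethod
    def from_code(cls, code: str) -> "RiskClass":
        try:
            return cls[code]
        except KeyError:
            raise ValueError(f"unknown risk class {code!r}") from None


@dataclasses.dataclass(frozen=True)
class LatitudeCuts:
    """Per-horizon latitude cut points: HR at/below c_hr, LR above c_mr."""

    cuts: Mapping[int, tuple[float, float]]  # horizon -> (c_hr, c_mr)

    def __post_init__(self) -> None:
        for h, (c_hr, c_mr) in self.cuts.items():
            if not c_hr < c_mr:
                raise ValueError(f"horizon {h}: need c_hr < c_mr, got {c_hr} >= {c_mr}")

    def at(self, horizon: int) -> tuple[float, float]:
        if horizon not in self.cuts:
            raise ValueError(f"unknown horizon {horizon}; have {sorted(self.cuts)}")
        return self.cuts[horizon]


@dataclasses.dataclass(frozen=True)
class BufferZone:
    """Geodesic circular risk zone around a country centroid."""

    country: str
    lon: float
    lat: float
    risk: RiskClass
    horizon: int
    radius_km: float


def _column(horizon: int) -> str:
    return f"risk_{horizon}"


def calibrate_latitude_cuts(fixture: pd.DataFrame, horizons: Iterable[int] = HORIZONS) -> LatitudeCuts:
    """Midpoint latitude cuts separating HR/MR/LR at each horizon.

    c_hr is the midpoint between the highest-latitude HR country and the
    lowest-latitude MR country; c_mr likewise between MR and LR.  Raises
    :class:`CalibrationError` (naming the countries) when the classes
    overlap in latitude.
    """
    cuts: dict[int, tuple[float, float]] = {}
    for h in horizons:
        col = _column(h)
        groups = {
            cls: fixture.loc[fixture[col] == cls.name, ["country", "lat"]]
            for cls in RiskClass
        }
        for cls in RiskClass:
            if groups[cls].empty:
                raise CalibrationError(f"horizon {h}: no {cls.name} country in fixture")
        pairs = ((RiskClass.HR, RiskClass.MR), (RiskClass.MR, RiskClass.LR))
        cut_vals = []
        for lower_cls, upper_cls in pairs:
            lo_max = groups[lower_cls].loc[groups[lower_cls]["lat"].idxmax()]
            hi_min = groups[upper_cls].loc[groups[upper_cls]["lat"].idxmin()]
            if lo_max["lat"] >= hi_min["lat"]:
                raise CalibrationError(
                    f"horizon {h}: {lower_cls.name}/{upper_cls.name} not latitude-"
                    f"separable: {lo_max['country']} ({lo_max['lat']}) vs "
                    f"{hi_min['country']} ({hi_min['lat']})"
                )
            cut_vals.append((lo_max["lat"] + hi_min["lat"]) / 2.0)
        cuts[h] = (cut_vals[0], cut_vals[1])
    return LatitudeCuts(cuts)


def classify_country(lat: float, horizon: int, cuts: LatitudeCuts) -> RiskClass:
    """HR if lat ≤ c_hr, MR if c_hr < lat ≤ c_mr, LR otherwise."""
    c_hr, c_mr = cuts.at(horizon)
    if lat <= c_hr:
        return RiskClass.HR
    if lat <= c_mr:
        return RiskClass.MR
    return RiskClass.LR


def risk_table(fixture: pd.DataFrame, cuts: LatitudeCuts) -> tuple[pd.DataFrame, dict[int, tuple[int, int]]]:
    """Predicted classes per country/horizon plus per-horizon agreement.

    Returns (table, agreement) where agreement maps horizon ->
    (n_matching, n_countries) against the fixture's printed classes.
    """
    out = fixture.copy()
    agreement: dict[int, tuple[int, int]] = {}
    for h in cuts.cuts:
        pred = [classify_country(lat, h, cuts).name for lat in out["lat"]]
        out[f"pred_{h}"] = pred
        col = _column(h)
        if col in out.columns:
            n_ok = int((out[col] == out[f"pred_{h}"]).sum())
            agreement[h] = (n_ok, len(out))
            out[f"agree_{h}"] = out[col] == out[f"pred_{h}"]
    return out, agreement


def default_radius_rule(risk: RiskClass, horizon: int) -> float:
    """Buffer radius (km): HR 300 / MR 200 / LR 100 at 2034, +50% at 2054, +100% at 2074."""
    base = {RiskClass.HR: 300.0, RiskClass.MR: 200.0, RiskClass.LR: 100.0}[risk]
    factor = {2034: 1.0, 2054: 1.5, 2074: 2.0}
    if horizon not in factor:
        raise ValueError(f"unknown horizon {horizon}")
    return base * factor[horizon]


def buffer_zones(
    fixture: pd.DataFrame,
    horizon: int,
    radius_rule: Callable[[RiskClass, int], float] = default_radius_rule,
    include: tuple[RiskClass, ...] = (RiskClass.HR, RiskClass.MR),
) -> list[BufferZone]:
    """Circular risk zones around at-risk (by default HR and MR) centroids."""
    col = _column(horizon)
    zones = []
    for _, row in fixture.iterrows():
        cls = RiskClass.from_code(row[col])
        if cls not in include:
            continue
        zones.append(
            BufferZone(
                country=row["country"],
                lon=float(row["lon"]),
                lat=float(row["lat"]),
                risk=cls,
                horizon=horizon,
                radius_km=radius_rule(cls, horizon),
            )
        )
    return zones


def buffer_zones_geojson(zones: Iterable[BufferZone], n_points: int = 96) -> dict:
    """GeoJSON FeatureCollection of geodesic buffer circles."""
    features = []
    for z in zones:
        poly = geodesic_circle(z.lon, z.lat, z.radius_km, n_points=n_points)
        features.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "Polygon",
                    "coordinates": [[list(c) for c in poly.exterior.coords]],
                },
                "properties": {
                    "country": z.country,
                    "risk": z.risk.name,
                    "horizon": z.horizon,
                    "radius_km": z.radius_km,
                },
            }
        )
    return {"type": "FeatureCollection", "features": features}


def joint_series(
    schedule: WarmingSchedule,
    maize_curve: MaizeGrowthCurve,
    spread: pd.DataFrame,
    years: Iterable[int] = range(2024, 2055),
) -> pd.DataFrame:
    """Aligned annual table: ΔT (°C), maize area (k ha), spread (% of suitable).

    ``spread`` must carry ``year`` and ``spread_pct`` columns covering the
    requested years.
    """
    years = list(years)
    have = set(spread["year"])
    missing = [y for y in years if y not in have]
    if missing:
        raise ValueError(f"spread series missing years {missing}")
    by_year = spread.set_index("year")["spread_pct"]
    return pd.DataFrame(
        {
            "year": years,
            "delta_t_c": [schedule.delta(y) for y in years],
            "maize_area_kha": [project_area(y, maize_curve) for y in years],
            "spread_pct": [float(by_year[y]) for y in years],
        }
    )
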