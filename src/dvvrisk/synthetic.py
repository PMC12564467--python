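"""Synthetic inputs: gridded climate with E-OBS-like structure, presence
histories, and the packaged country fixtures.

The climate generator produces the statistical features the downstream
analysis assumes rather than any particular weather: a latitude-dominated
climatology with a July-peaked seasonal cycle, a linear decadal warming
trend centred on the 1991–2020 reference period, spatially smooth
inter-annual anomaly fields, and seeded cell-level noise.  Identical seeds
give bit-identical output.
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .geo import haversine_km
from .grids import GridSpec, MonthlyClimateGrid

__all__ = [
    "ClimatologyParams",
    "PresenceRecord",
    "PRESENCE_STATUSES",
    "FixtureError",
    "SERBIA_ORIGIN",
    "generate_climatology",
    "generate_annual_series",
    "generate_presence_history",
    "load_centroid_fixture",
    "load_maize_area_fixture",
]

#: First-detection locale used as the default spread origin (near Belgrade).
SERBIA_ORIGIN = (20.5, 44.8)

#: The closed six-value presence-status vocabulary.
PRESENCE_STATUSES = (
    "absent",
    "widespread",
    "restricted",
    "few_occurrences",
    "eradicated",
    "transient",
)


class FixtureError(ValueError):
    """A packaged fixture failed its integrity check."""


@dataclasses.dataclass(frozen=True)
class ClimatologyParams:
    """Parameters of the synthetic monthly climatology (all temperatures °C).

    ``sea_level_july_temp`` anchors July at latitude 45°N; ``lapse_per_lat``
    is the meridional gradient; ``seasonal_amplitude`` the half-range of the
    annual cycle; ``noise_sd`` cell-level Gaussian noise; ``anomaly_sd`` the
    standard deviation of the smooth inter-annual anomaly fields;
    ``trend_per_year`` the warming trend over 1991–2024, centred on 2005.5 so
    the 1991–2020 mean reproduces the climatology.
    """

    sea_level_july_temp: float = 22.0
    lapse_per_lat: float = 0.7
    seasonal_amplitude: float = 10.0
    noise_sd: float = 0.5
    anomaly_sd: float = 0.3
    trend_per_year: float = 0.04
    seed: int = 42

    def __post_init__(self) -> None:
        for name in ("lapse_per_lat", "seasonal_amplitude", "noise_sd", "anomaly_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclasses.dataclass(frozen=True)
class PresenceRecord:
    """One country-year presence status record (EPPO-style vocabulary)."""

    country: str
    year: int
    status: str

    def __post_init__(self) -> None:
        if self.status not in PRESENCE_STATUSES:
            raise ValueError(f"unknown status {self.status!r}")


#: Reference year such that the linear trend integrates to zero over 1991–2020.
_TREND_CENTER = 2005.5


def generate_climatology(
    grid: GridSpec = GridSpec(), params: ClimatologyParams = ClimatologyParams()
) -> MonthlyClimateGrid:
    """Synthetic 12-month reference climatology.

    T(lat, m) = a − lapse·lat + A·cos(2π(m−7)/12) + ε with the intercept
    ``a`` fixed so that noise-free July at 45°N equals
    ``sea_level_july_temp``.  With zero noise, July is the warmest month
    everywhere and every month is strictly decreasing in latitude.
    """
    lats = grid.lats()
    months = np.arange(1, 13)
    a = params.sea_level_july_temp + params.lapse_per_lat * 45.0 - params.seasonal_amplitude
    seasonal = params.seasonal_amplitude * np.cos(2 * np.pi * (months - 7) / 12.0)
    tmean = (
        a
        + seasonal[:, None, None]
        - params.lapse_per_lat * lats[None, :, None]
        + np.zeros((12, grid.nlat, grid.nlon))
    )
    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        tmean = tmean + rng.normal(0.0, params.noise_sd, size=tmean.shape)
    return MonthlyClimateGrid(grid=grid, tmean=tmean, label="climatology-1991-2020")


def _smooth_anomaly_field(grid: GridSpec, rng: np.random.Generator, sd: float) -> np.ndarray:
    """Low-frequency smooth surface with ~zero mean and standard deviation sd.

    A few-term separable sinusoid basis with seeded coefficients, so warm and
    cool regions exist by construction.
    """
    if sd == 0:
        return np.zeros(grid.shape)
    lon2d, lat2d = grid.mesh()
    u = (lon2d - grid.lon_min) / (grid.lon_max - grid.lon_min)
    v = (lat2d - grid.lat_min) / (grid.lat_max - grid.lat_min)
    field = np.zeros(grid.shape)
    n_terms = 4
    coeffs = rng.normal(0.0, 1.0, size=n_terms)
    freqs = rng.integers(1, 4, size=(n_terms, 2))
    phases = rng.uniform(0, 2 * np.pi, size=(n_terms, 2))
    for c, (fu, fv), (pu, pv) in zip(coeffs, freqs, phases):
        field += c * np.sin(2 * np.pi * fu * u + pu) * np.sin(2 * np.pi * fv * v + pv)
    s = field.std()
    if s > 0:
        field *= sd / s
    return field


def generate_annual_series(
    grid: GridSpec = GridSpec(),
    params: ClimatologyParams = ClimatologyParams(),
    years: Iterable[int] = range(1991, 2025),
) -> dict[int, MonthlyClimateGrid]:
    """Annual monthly-mean grids: climatology + trend + smooth anomaly field.

    The trend is centred on 2005.5, so the 1991–2020 mean of the series
    equals the climatology up to the (zero-mean) anomaly fields.
    """
    years = list(years)
    if not years:
        raise ValueError("empty year range")
    if any(y < 1991 or y > 2100 for y in years):
        raise ValueError("years must lie within [1991, 2100]")
    clim = generate_climatology(grid, params)
    out: dict[int, MonthlyClimateGrid] = {}
    for year in years:
        rng = np.random.default_rng([params.seed, year])
        anomaly = _smooth_anomaly_field(grid, rng, params.anomaly_sd)
        offset = params.trend_per_year * (year - _TREND_CENTER)
        tmean = clim.tmean + offset + anomaly[None, :, :]
        out[year] = MonthlyClimateGrid(grid=grid, tmean=tmean, label=str(year))
    return out


def generate_presence_history(
    origin: tuple[float, float] = SERBIA_ORIGIN,
    years: Iterable[int] = range(1992, 2025),
    spread_rate: float = 0.8,
    seed: int = 42,
    year_jitter: int = 0,
    countries: pd.DataFrame | None = None,
) -> tuple[list[PresenceRecord], pd.DataFrame]:
    """Country presence histories radiating from the first-detection origin.

    Each country's first-detection year grows with its centroid's
    great-circle distance (in degrees of arc) from ``origin`` at
    ``spread_rate`` degrees/year; after detection the status matures from
    ``few_occurrences`` through ``restricted`` to ``widespread``.  The
    nearest country to the origin is detected in the first year regardless
    of rate; with ``spread_rate = 0`` it is the only country ever present.
    ``year_jitter > 0`` adds seeded integer noise to detection years (the
    noise-free default keeps detection year non-decreasing in distance).

    Returns the record list and a point table (country, lon, lat,
    first_detection_year) for the countries detected within ``years``.
    """
    if spread_rate < 0:
        raise ValueError("spread_rate must be >= 0")
    years = list(years)
    if not years:
        raise ValueError("empty year range")
    if countries is None:
        countries = load_centroid_fixture()
        # excluded from the 2024 distribution analysis in the source data
        countries = countries[countries["country"] != "Moldova"].reset_index(drop=True)
    origin_year = years[0]
    dist_km = haversine_km(origin[0], origin[1], countries["lon"].to_numpy(), countries["lat"].to_numpy())
    dist_deg = np.asarray(dist_km) / 111.19  # great-circle degrees of arc
    rng = np.random.default_rng(seed)
    detection: dict[str, float] = {}
    nearest = countries["country"].iloc[int(np.argmin(dist_deg))]
    for name, d in zip(countries["country"], dist_deg):
        if name == nearest:
            detection[name] = origin_year
        elif spread_rate == 0:
            detection[name] = float("inf")
        else:
            year = origin_year + int(np.ceil(d / spread_rate))
            if year_jitter:
                year += int(rng.integers(-year_jitter, year_jitter + 1))
            detection[name] = max(year, origin_year)

    records: list[PresenceRecord] = []
    for name in countries["country"]:
        det = detection[name]
        for year in years:
            age = year - det
            if age < 0:
                status = "absent"
            elif age < 5:
                status = "few_occurrences"
            elif age < 15:
                status = "restricted"
            else:
                status = "widespread"
            records.append(PresenceRecord(country=name, year=year, status=status))

    present = countries[[d <= years[-1] for d in (detection[c] for c in countries["country"])]].copy()
    present["first_detection_year"] = [int(detection[c]) for c in present["country"]]
    return records, present.reset_index(drop=True)


def _data_path(name: str):
    return resources.files("dvvrisk.data").joinpath(name)


def load_centroid_fixture() -> pd.DataFrame:
    """The 29-country centroid/risk table (lon, lat, class per horizon)."""
    with resources.as_file(_data_path("table2_centroids.csv")) as p:
        df = pd.read_csv(p)
    if len(df) != 29:
        raise FixtureError(f"centroid fixture must have 29 rows, found {len(df)}")
    expected = {"country", "lon", "lat", "risk_2034", "risk_2054", "risk_2074"}
    if set(df.columns) != expected:
        raise FixtureError(f"centroid fixture columns {list(df.columns)} != {sorted(expected)}")
    for col in ("risk_2034", "risk_2054", "risk_2074"):
        bad = set(df[col]) - {"LR", "MR", "HR"}
        if bad:
            raise FixtureError(f"unknown risk codes {bad} in {col}")
    return df


def load_maize_area_fixture() -> pd.DataFrame:
    """Per-country maize areas: two source-year values in million ha.

    Romania's 2.5 Mha is the published worked example; the other values are
    synthetic but chosen so the published intensity groupings hold
    (intensive >1000 k ha: Ukraine, Romania, France, Italy, Hungary;
    moderate 500–1000 k ha: Germany, Poland, Spain, Bulgaria, Austria;
    weak <500 k ha elsewhere).
    """
    with resources.as_file(_data_path("maize_areas.csv")) as p:
        df = pd.read_csv(p)
    if df[["mha_y1", "mha_y2"]].lt(0).any().any():
        raise FixtureError("maize areas must be non-negative")
    return df


def presence_points_geojson(points: pd.DataFrame) -> dict:
    """GeoJSON FeatureCollection for a presence point table."""
    features = []
    for _, row in points.iterrows():
        props = {k: (int(v) if isinstance(v, np.integer) else v) for k, v in row.items() if k not in ("lon", "lat")}
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [float(row["lon"]), float(row["lat"])]},
                "properties": props,
            }
        )
    return {"type": "FeatureCollection", "features": features}
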