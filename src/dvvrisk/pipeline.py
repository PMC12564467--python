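"""End-to-end pipeline: synthetic climate → anomalies → suitability →
spread → maize/risk outputs, with a flat-text config and a manifest.

Every output is a plain-text format the package's own readers re-read
(Esri ASCII grids, CSV, GeoJSON), and two runs from the same config file
are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import shutil
from pathlib import Path

import numpy as np

from . import synthetic
from .climate import PERIODS, ReferencePeriod, SeasonWindow, WarmingSchedule, anomaly_map
from .grids import GridSpec, write_ascii_grid
from .maize import MaizeGrowthCurve, area_table
from .risk import (
    buffer_zones,
    buffer_zones_geojson,
    calibrate_latitude_cuts,
    joint_series,
    risk_table,
)
from .spread import (
    DispersalConfig,
    LogisticParams,
    affected_categories,
    logistic_fraction,
    simulate_spread,
    spread_series,
)
from .suitability import MaizeThresholds, PestThresholds, maize_suitability_mask, pest_suitability_mask
from .synthetic import ClimatologyParams, SERBIA_ORIGIN

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger(__name__)

#: Years Fig.-4-style state and category rasters are written for.
STATE_YEARS = (2029, 2034, 2039, 2049, 2054)

#: Known inconsistencies in the source tables, echoed into every manifest.
SOURCE_NOTES = [
    "warming step: body text says 0.5 C / 5 yr, the schedule table says 0.2 C / 5 yr; the table is used",
    "activity threshold: 15 C is the warm-season overlap threshold, 12.5 C the monthly suitability threshold",
    "risk-table asterisk typos (North Macedonia 2054, Poland 2034, Spain 2034) read by letter code",
    "affected-age bands (5/15 yr) and buffer radii (300/200/100 km, x1.5/x2) are package defaults",
]


class PipelineError(RuntimeError):
    """A pipeline stage failed; message names the stage."""


@dataclasses.dataclass
class PipelineConfig:
    """Flat, serializable configuration for :func:`run_pipeline`."""

    grid: GridSpec = dataclasses.field(default_factory=GridSpec)
    climatology: ClimatologyParams = dataclasses.field(default_factory=ClimatologyParams)
    pest: PestThresholds = dataclasses.field(default_factory=PestThresholds)
    maize_thresholds: MaizeThresholds = dataclasses.field(default_factory=MaizeThresholds)
    schedule: WarmingSchedule = dataclasses.field(default_factory=WarmingSchedule)
    logistic: LogisticParams = dataclasses.field(default_factory=LogisticParams)
    dispersal: DispersalConfig = dataclasses.field(default_factory=DispersalConfig)
    maize_curve: MaizeGrowthCurve = dataclasses.field(default_factory=MaizeGrowthCurve)
    horizons: tuple[int, ...] = (2034, 2054, 2074)
    spread_years: tuple[int, int] = (2024, 2054)
    origin: tuple[float, float] = SERBIA_ORIGIN
    seed: int = 42
    outdir: str = "results/pipeline"

    # --- flat key=value round trip -------------------------------------
    def to_flat(self) -> dict[str, str]:
        flat: dict[str, str] = {}

        def put(prefix: str, obj) -> None:
            for f in dataclasses.fields(obj):
                v = getattr(obj, f.name)
                if dataclasses.is_dataclass(v):
                    put(f"{prefix}{f.name}.", v)
                else:
                    flat[f"{prefix}{f.name}"] = repr(v)

        for name in (
            "grid",
            "climatology",
            "pest",
            "maize_thresholds",
            "schedule",
            "logistic",
            "dispersal",
            "maize_curve",
        ):
            put(f"{name}.", getattr(self, name))
        flat["horizons"] = repr(tuple(self.horizons))
        flat["spread_years"] = repr(tuple(self.spread_years))
        flat["origin"] = repr(tuple(self.origin))
        flat["seed"] = repr(self.seed)
        flat["outdir"] = repr(self.outdir)
        return flat

    def to_text(self) -> str:
        return "\n".join(f"{k} = {v}" for k, v in sorted(self.to_flat().items())) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "PipelineConfig":
        import ast

        flat: dict[str, object] = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            flat[key.strip()] = ast.literal_eval(value.strip())

        def build(prefix: str, typ):
            kwargs = {}
            for f in dataclasses.fields(typ):
                full = f"{prefix}{f.name}"
                if f.name == "window":
                    kwargs[f.name] = build(f"{full}.", SeasonWindow)
                elif full in flat:
                    kwargs[f.name] = flat[full]
            return typ(**kwargs)

        return cls(
            grid=build("grid.", GridSpec),
            climatology=build("climatology.", ClimatologyParams),
            pest=build("pest.", PestThresholds),
            maize_thresholds=build("maize_thresholds.", MaizeThresholds),
            schedule=build("schedule.", WarmingSchedule),
            logistic=build("logistic.", LogisticParams),
            dispersal=build("dispersal.", DispersalConfig),
            maize_curve=build("maize_curve.", MaizeGrowthCurve),
            horizons=tuple(flat.get("horizons", (2034, 2054, 2074))),
            spread_years=tuple(flat.get("spread_years", (2024, 2054))),
            origin=tuple(flat.get("origin", SERBIA_ORIGIN)),
            seed=int(flat.get("seed", 42)),
            outdir=str(flat.get("outdir", "results/pipeline")),
        )


def _seed_mask_near_origin(suitable: np.ndarray, grid: GridSpec, origin: tuple[float, float], n_cells: int) -> np.ndarray:
    """The n suitable cells nearest the origin (ties: lat, then lon)."""
    from .geo import haversine_km

    iy, ix = np.nonzero(suitable)
    lats, lons = grid.lats(), grid.lons()
    d = haversine_km(origin[0], origin[1], lons[ix], lats[iy])
    order = np.lexsort((lons[ix], lats[iy], d))[:n_cells]
    mask = np.zeros_like(suitable, dtype=bool)
    mask[iy[order], ix[order]] = True
    return mask


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the artifact bundle under ``config.outdir``.

    Returns the manifest dict.  Any stage error removes partial outputs and
    raises :class:`PipelineError` naming the stage.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_flat(),
        "notes": SOURCE_NOTES,
        "outputs": [],
    }

    def emit(path: Path) -> None:
        manifest["outputs"].append(str(path.relative_to(out)))

    stage = "init"
    try:
        stage = "climate-series"
        logger.info("stage %s: synthetic climatology and 1991-2024 series", stage)
        series = synthetic.generate_annual_series(config.grid, config.climatology, range(1991, 2025))

        stage = "anomalies"
        logger.info("stage %s: DAT rasters for P1-P6", stage)
        ref = ReferencePeriod()
        for period in PERIODS:
            dat = anomaly_map(series, period, ref)
            p = out / f"dat_{period.label}_{period.start}-{period.end}.asc"
            write_ascii_grid(p, dat, config.grid)
            emit(p)

        stage = "suitability"
        logger.info("stage %s: pest and maize masks per horizon", stage)
        clim = synthetic.generate_climatology(config.grid, config.climatology)
        horizon_masks: dict[int, np.ndarray] = {}
        for h in config.horizons:
            warmed = clim.shifted(config.schedule.delta_vs_present(h))
            activity, establishment = pest_suitability_mask(warmed, config.pest)
            maize_mask = maize_suitability_mask(warmed, config.maize_thresholds)
            horizon_masks[h] = establishment.mask
            for name, m in (
                ("pest_activity", activity),
                ("pest_establishment", establishment),
                ("maize", maize_mask),
            ):
                p = out / f"suitability_{name}_{h}.asc"
                write_ascii_grid(p, m.mask.astype(float), config.grid)
                emit(p)

        stage = "spread"
        y0, y1 = config.spread_years
        logger.info("stage %s: cellular spread %d-%d", stage, y0, y1)
        years = list(range(y0, y1 + 1))
        suit_by_year = {}
        for y in years:
            warmed = clim.shifted(config.schedule.delta_vs_present(y))
            _, establishment = pest_suitability_mask(warmed, config.pest)
            suit_by_year[y] = establishment.mask
        n0 = int(round(config.logistic.p0 * suit_by_year[y0].sum()))
        seed_mask = _seed_mask_near_origin(suit_by_year[y0], config.grid, config.origin, n0)
        states = simulate_spread(seed_mask, suit_by_year, config.grid, years, config.logistic, config.dispersal)
        by_year = {st.horizon: st for st in states}
        for y in STATE_YEARS:
            if y not in by_year:
                continue
            p = out / f"spread_state_{y}.asc"
            write_ascii_grid(p, by_year[y].year_first.astype(float), config.grid)
            emit(p)
            p = out / f"spread_categories_{y}.asc"
            write_ascii_grid(p, affected_categories(by_year[y]).astype(float), config.grid)
            emit(p)
        series_df = spread_series(states, suit_by_year[y1])
        p = out / "spread_series.csv"
        series_df.to_csv(p, index=False)
        emit(p)

        stage = "maize"
        logger.info("stage %s: area table and joint series", stage)
        areas = area_table(synthetic.load_maize_area_fixture())
        p = out / "maize_areas.csv"
        areas.to_csv(p, index=False)
        emit(p)
        fig5 = joint_series(config.schedule, config.maize_curve, series_df, years)
        p = out / "joint_series.csv"
        fig5.to_csv(p, index=False)
        emit(p)

        stage = "risk"
        logger.info("stage %s: country risk table and buffer zones", stage)
        fixture = synthetic.load_centroid_fixture()
        cuts = calibrate_latitude_cuts(fixture)
        table, agreement = risk_table(fixture, cuts)
        p = out / "risk_table.csv"
        table.to_csv(p, index=False)
        emit(p)
        manifest["risk_agreement"] = {str(h): list(v) for h, v in agreement.items()}
        manifest["latitude_cuts"] = {str(h): list(cuts.at(h)) for h in cuts.cuts}
        for h in config.horizons:
            zones = buffer_zones(fixture, h)
            p = out / f"buffer_zones_{h}.geojson"
            p.write_text(json.dumps(buffer_zones_geojson(zones), indent=1, sort_keys=True))
            emit(p)

        stage = "manifest"
        manifest["spread_pct_final"] = float(series_df["spread_pct"].iloc[-1])
        manifest["logistic_pct_final"] = 100.0 * logistic_fraction(y1 - y0, config.logistic)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    except Exception as exc:
        shutil.rmtree(out, ignore_errors=True)
        raise PipelineError(f"stage '{stage}' failed: {exc}") from exc
    return manifest
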