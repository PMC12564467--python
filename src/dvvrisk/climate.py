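"""Warming schedule, temperature anomalies (DAT), warm-season statistics,
and growing-degree-day accumulation.

The projection side of the analysis is deliberately simple: future warming is
a single anchored linear schedule (ΔT = +1.4 °C at 2024 rising by 0.2 °C per
5 years, i.e. +2.6 °C at 2054), applied uniformly to a reference climatology.
Historical variability is handled separately, as anomalies of multi-year
means against the 1991–2020 reference period (the "DAT" of the analysis).
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .grids import GridSpec, MonthlyClimateGrid

__all__ = [
    "DAYS_IN_MONTH",
    "WarmingSchedule",
    "ReferencePeriod",
    "PeriodDefinition",
    "PERIODS",
    "SeasonWindow",
    "CoverageError",
    "warming_delta",
    "apply_warming",
    "annual_mean",
    "anomaly_map",
    "gdd",
    "warm_season_mean",
    "presence_anomaly_overlap",
]

# Non-leap calendar; monthly sums use month lengths, no daily downscaling.
DAYS_IN_MONTH = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])


class CoverageError(ValueError):
    """A climate series does not cover the years an operation needs."""


@dataclasses.dataclass(frozen=True)
class WarmingSchedule:
    """Anchored linear ΔT-versus-year rule.

    ΔT(y) = anchor_delta + (step_per_5yr / 5) · (y − anchor_year), valid for
    y ≥ anchor_year.  ΔT is measured against the pre-industrial reference, so
    the anchor value (+1.4 °C at 2024) is the starting point, and warming
    *relative to the present climate* is ΔT(y) − anchor_delta.
    """

    anchor_year: int = 2024
    anchor_delta: float = 1.4
    step_per_5yr: float = 0.2

    def delta(self, year: int) -> float:
        """ΔT (°C) versus pre-industrial at ``year``; extrapolates past 2054."""
        if year < self.anchor_year:
            raise ValueError(
                f"schedule starts at {self.anchor_year}; historical years use "
                "anomalies, not the schedule"
            )
        return self.anchor_delta + (self.step_per_5yr / 5.0) * (year - self.anchor_year)

    def delta_vs_present(self, year: int) -> float:
        """Extra warming (°C) at ``year`` relative to the anchor year."""
        return self.delta(year) - self.anchor_delta

    def table(self, start: int | None = None, end: int = 2054, step: int = 5) -> pd.DataFrame:
        """The printed 5-yearly schedule as a (year, delta_c) table."""
        start = self.anchor_year if start is None else start
        years = list(range(start, end + 1, step))
        return pd.DataFrame({"year": years, "delta_c": [self.delta(y) for y in years]})


def warming_delta(year: int, schedule: WarmingSchedule | None = None) -> float:
    """ΔT (°C) of the default (or given) warming schedule at ``year``."""
    return (schedule or WarmingSchedule()).delta(year)


@dataclasses.dataclass(frozen=True)
class ReferencePeriod:
    """Inclusive year range anomalies are measured against (1991–2020)."""

    start: int = 1991
    end: int = 2020

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("reference period start must be <= end")

    @property
    def years(self) -> range:
        return range(self.start, self.end + 1)


@dataclasses.dataclass(frozen=True)
class PeriodDefinition:
    """A cumulative analysis interval (inclusive) labelled P1..P6."""

    label: str
    start: int
    end: int

    @property
    def years(self) -> range:
        return range(self.start, self.end + 1)


#: The six cumulative intervals the anomaly maps are produced for.
PERIODS: tuple[PeriodDefinition, ...] = (
    PeriodDefinition("P1", 1991, 1992),
    PeriodDefinition("P2", 1992, 2002),
    PeriodDefinition("P3", 1992, 2012),
    PeriodDefinition("P4", 1992, 2020),
    PeriodDefinition("P5", 1992, 2022),
    PeriodDefinition("P6", 1992, 2024),
)


@dataclasses.dataclass(frozen=True)
class SeasonWindow:
    """Growing-season month window (1-based, inclusive); default Apr–Sep.

    ``activity_mean_threshold`` is the 15 °C warm-season mean used in the
    presence/anomaly overlap analysis (distinct from the 12.5 °C monthly
    activity threshold used for suitability).
    """

    start_month: int = 4
    end_month: int = 9
    activity_mean_threshold: float = 15.0

    def __post_init__(self) -> None:
        if not 1 <= self.start_month <= self.end_month <= 12:
            raise ValueError("need 1 <= start_month <= end_month <= 12")

    @property
    def months(self) -> range:
        return range(self.start_month, self.end_month + 1)

    @property
    def length(self) -> int:
        return self.end_month - self.start_month + 1


def apply_warming(grid: MonthlyClimateGrid, delta: float) -> MonthlyClimateGrid:
    """Shift every cell of every month by exactly ``delta`` °C."""
    if not math.isfinite(delta):
        raise ValueError("delta must be finite")
    return grid.shifted(delta)


def annual_mean(grid: MonthlyClimateGrid, day_weighted: bool = False) -> np.ndarray:
    """Per-cell annual mean temperature.

    Default is the unweighted mean of the 12 monthly means; ``day_weighted``
    weights by non-leap month lengths.
    """
    if day_weighted:
        w = DAYS_IN_MONTH / DAYS_IN_MONTH.sum()
        return np.tensordot(w, grid.tmean, axes=(0, 0))
    return grid.tmean.mean(axis=0)


def anomaly_map(
    series: Mapping[int, MonthlyClimateGrid],
    period: PeriodDefinition,
    ref: ReferencePeriod = ReferencePeriod(),
    day_weighted: bool = False,
    window: SeasonWindow | None = None,
) -> np.ndarray:
    """DAT raster: mean temperature over ``period`` minus the reference mean.

    ``window=None`` (default) uses annual means; passing a
    :class:`SeasonWindow` instead computes warm-season anomalies.
    """
    missing = [y for y in (*period.years, *ref.years) if y not in series]
    if missing:
        raise CoverageError(f"series missing years: {sorted(set(missing))}")

    def cell_mean(year: int) -> np.ndarray:
        g = series[year]
        if window is None:
            return annual_mean(g, day_weighted=day_weighted)
        return warm_season_mean(g, window)

    period_mean = np.mean([cell_mean(y) for y in period.years], axis=0)
    ref_mean = np.mean([cell_mean(y) for y in ref.years], axis=0)
    return period_mean - ref_mean


def gdd(monthly_means: np.ndarray | Sequence[float], base: float = 10.0) -> np.ndarray | float:
    """Growing degree days from 12 monthly means: Σ max(0, T_m − base) · days_m.

    Accepts a 12-vector (returns a float) or a ``(12, nlat, nlon)`` stack
    (returns a raster).
    """
    t = np.asarray(monthly_means, dtype=float)
    if t.shape[0] != 12:
        raise ValueError(f"expected 12 monthly values, got {t.shape[0]}")
    excess = np.clip(t - base, 0.0, None)
    days = DAYS_IN_MONTH.reshape((12,) + (1,) * (t.ndim - 1))
    out = (excess * days).sum(axis=0)
    return float(out) if out.ndim == 0 else out


def warm_season_mean(grid: MonthlyClimateGrid, window: SeasonWindow = SeasonWindow()) -> np.ndarray:
    """Per-cell mean of monthly means over the season window."""
    idx = [m - 1 for m in window.months]
    return grid.tmean[idx].mean(axis=0)


def presence_anomaly_overlap(
    points: Sequence[tuple[float, float]],
    dat: np.ndarray,
    grid: GridSpec,
    threshold: float,
) -> float:
    """Fraction of presence points whose DAT cell value is ≥ ``threshold``.

    Points outside the grid are excluded from the denominator with a warning.
    With no usable points the result is undefined and NaN is returned.
    """
    hits = 0
    n = 0
    for lon, lat in points:
        if not grid.contains(lon, lat):
            warnings.warn(f"presence point ({lon}, {lat}) outside grid; excluded")
            continue
        iy, ix = grid.cell_index(lon, lat)
        n += 1
        if dat[iy, ix] >= threshold:
            hits += 1
    if n == 0:
        warnings.warn("no presence points inside grid; overlap undefined")
        return float("nan")
    return hits / n
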