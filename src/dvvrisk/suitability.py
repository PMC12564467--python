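"""Thermal-envelope suitability: beetle activity/establishment and maize.

A cell is suitable for beetle activity (establishment) when its monthly mean
reaches 12.5 °C (9 °C) for at least two consecutive growing-season months
(April–September); comparisons are inclusive.  Maize suitability combines a
heat-sum requirement (≥1000 GDD, base 10 °C), a germination month (some
window month mean ≥10 °C) and a heat-stress exclusion (no window month
maximum above 35 °C).
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from shapely import contains_xy
from shapely.geometry.base import BaseGeometry

from .climate import SeasonWindow, gdd
from .grids import GridSpec, MonthlyClimateGrid

__all__ = [
    "PestThresholds",
    "MaizeThresholds",
    "SuitabilityMask",
    "persistent_exceedance",
    "pest_suitability_mask",
    "maize_suitability_mask",
    "suitable_fraction",
]


@dataclasses.dataclass(frozen=True)
class PestThresholds:
    """Thermal thresholds for the beetle (°C) and the persistence rule."""

    activity_min: float = 12.5
    establishment_min: float = 9.0
    optimal_lo: float = 18.0
    optimal_hi: float = 32.0
    persistence_months: int = 2
    window: SeasonWindow = SeasonWindow()

    def __post_init__(self) -> None:
        if not (self.establishment_min < self.activity_min < self.optimal_lo < self.optimal_hi):
            raise ValueError("need establishment_min < activity_min < optimal_lo < optimal_hi")
        if self.persistence_months < 1:
            raise ValueError("persistence_months must be >= 1")


@dataclasses.dataclass(frozen=True)
class MaizeThresholds:
    """Maize crop thresholds: germination, optimum, heat stress, GDD range."""

    germination_min: float = 10.0
    optimal_lo: float = 24.0
    optimal_hi: float = 30.0
    heat_stress_max: float = 35.0
    gdd_lo: float = 1000.0
    gdd_hi: float = 1400.0
    gdd_base: float = 10.0
    window: SeasonWindow = SeasonWindow()

    def __post_init__(self) -> None:
        if not (self.germination_min < self.optimal_lo < self.optimal_hi < self.heat_stress_max):
            raise ValueError("need germination_min < optimal_lo < optimal_hi < heat_stress_max")
        if self.gdd_lo > self.gdd_hi:
            raise ValueError("gdd_lo must be <= gdd_hi")


@dataclasses.dataclass
class SuitabilityMask:
    """Boolean raster plus the rule metadata that produced it."""

    mask: np.ndarray
    rule: dict

    @property
    def n_suitable(self) -> int:
        return int(self.mask.sum())


def _window_run(ok: np.ndarray, k: int) -> np.ndarray:
    """True where some run of >= k consecutive window months is all True.

    ``ok`` has the window-month axis first.
    """
    n = ok.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"need 1 <= k <= window length {n}, got k={k}")
    hit = np.zeros(ok.shape[1:] if ok.ndim > 1 else (), dtype=bool)
    for start in range(n - k + 1):
        hit = hit | ok[start : start + k].all(axis=0)
    return hit


def persistent_exceedance(
    monthly_means: Sequence[float] | np.ndarray,
    threshold: float,
    k_consecutive: int = 2,
    window: SeasonWindow = SeasonWindow(),
) -> bool:
    """True iff >= k consecutive window months all have mean >= threshold."""
    t = np.asarray(monthly_means, dtype=float)
    if t.shape[0] != 12:
        raise ValueError(f"expected 12 monthly values, got {t.shape[0]}")
    idx = [m - 1 for m in window.months]
    ok = t[idx] >= threshold
    return bool(_window_run(ok, k_consecutive))


def _persistence_grid(
    grid: MonthlyClimateGrid, threshold: float, k: int, window: SeasonWindow
) -> np.ndarray:
    idx = [m - 1 for m in window.months]
    ok = grid.tmean[idx] >= threshold
    return _window_run(ok, k)


def pest_suitability_mask(
    grid: MonthlyClimateGrid, thresholds: PestThresholds = PestThresholds()
) -> tuple[SuitabilityMask, SuitabilityMask]:
    """(activity, establishment) masks via the persistence rule.

    Because 12.5 > 9 with the same rule, activity ⊆ establishment.
    """
    k, window = thresholds.persistence_months, thresholds.window
    activity = SuitabilityMask(
        mask=_persistence_grid(grid, thresholds.activity_min, k, window),
        rule={
            "threshold_c": thresholds.activity_min,
            "persistence_months": k,
            "window": f"{window.start_month}-{window.end_month}",
            "kind": "activity",
        },
    )
    establishment = SuitabilityMask(
        mask=_persistence_grid(grid, thresholds.establishment_min, k, window),
        rule={
            "threshold_c": thresholds.establishment_min,
            "persistence_months": k,
            "window": f"{window.start_month}-{window.end_month}",
            "kind": "establishment",
        },
    )
    return activity, establishment


def maize_suitability_mask(
    grid: MonthlyClimateGrid,
    thresholds: MaizeThresholds = MaizeThresholds(),
    tmax_offset: float = 6.0,
) -> SuitabilityMask:
    """Maize mask: GDD ≥ gdd_lo AND a germination month AND no heat stress.

    Monthly maxima default to ``mean + tmax_offset`` when the grid carries
    no explicit tmax layers.  The lower GDD bound is the pass criterion
    (1000–1400 is a hybrid-dependent range); air temperature proxies soil
    temperature for germination.
    """
    heat = gdd(grid.tmean, base=thresholds.gdd_base)
    idx = [m - 1 for m in thresholds.window.months]
    germination = (grid.tmean[idx] >= thresholds.germination_min).any(axis=0)
    tmax = grid.tmax if grid.tmax is not None else grid.tmean + tmax_offset
    no_stress = ~(tmax[idx] > thresholds.heat_stress_max).any(axis=0)
    mask = (heat >= thresholds.gdd_lo) & germination & no_stress
    return SuitabilityMask(
        mask=mask,
        rule={
            "gdd_lo": thresholds.gdd_lo,
            "gdd_base": thresholds.gdd_base,
            "germination_min_c": thresholds.germination_min,
            "heat_stress_max_c": thresholds.heat_stress_max,
            "tmax_source": "explicit" if grid.tmax is not None else f"mean+{tmax_offset}",
            "kind": "maize",
        },
    )


def suitable_fraction(mask: SuitabilityMask | np.ndarray, region: BaseGeometry, grid: GridSpec) -> float:
    """Area-weighted (cos-latitude) suitable fraction of the region's cells."""
    m = mask.mask if isinstance(mask, SuitabilityMask) else np.asarray(mask, dtype=bool)
    lon2d, lat2d = grid.mesh()
    inside = contains_xy(region, lon2d.ravel(), lat2d.ravel()).reshape(grid.shape)
    if not inside.any():
        raise ValueError("region polygon does not overlap any grid cell")
    w = np.cos(np.radians(lat2d))
    return float((w * m)[inside].sum() / w[inside].sum())
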