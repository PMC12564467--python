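"""Logistic growth of the infested fraction and its cellular realization.

The infested fraction of climatically suitable area follows
P(t) = k / (1 + ((k − p0)/p0) e^{−rt}).  Defaults p0 = 0.40 at 2024 and
r = 0.1117 / yr are calibrated (see :func:`fit_logistic_rate`) so that
P reaches 95% of suitable area 30 years on, at 2054.  The spatial
realization fills the logistic target count by deterministic nearest-first
frontier growth within an annual dispersal radius; infestation is never
revoked.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import curve_fit
from scipy.spatial import cKDTree

from .geo import chord_to_arc_km, unit_vectors
from .grids import GridSpec

__all__ = [
    "LogisticParams",
    "DispersalConfig",
    "InfestationState",
    "CATEGORY_CODES",
    "logistic_fraction",
    "fit_logistic_rate",
    "fit_logistic_series",
    "simulate_spread",
    "affected_categories",
    "spread_series",
]

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class LogisticParams:
    """Logistic growth parameters: initial fraction, rate/yr, capacity."""

    p0: float = 0.40
    r: float = 0.1117
    k: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.p0 < self.k <= 1:
            raise ValueError("need 0 < p0 < k <= 1")
        if self.r < 0:
            raise ValueError("need r >= 0")


@dataclasses.dataclass(frozen=True)
class DispersalConfig:
    """Cellular spread constraint: annual radius (km) and tie-break order."""

    annual_radius_km: float = 50.0
    tie_break: str = "latlon"  # lexicographic (lat, lon)
    seed: int = 42

    def __post_init__(self) -> None:
        if self.annual_radius_km < 0:
            raise ValueError("annual_radius_km must be >= 0")


@dataclasses.dataclass
class InfestationState:
    """Per-cell year of first infestation (0 = never) at a horizon year."""

    year_first: np.ndarray
    horizon: int

    @property
    def infested(self) -> np.ndarray:
        return self.year_first > 0

    @property
    def n_infested(self) -> int:
        return int(self.infested.sum())


def logistic_fraction(t_years: float | np.ndarray, params: LogisticParams = LogisticParams()) -> float | np.ndarray:
    """Closed-form logistic P(t); strictly increasing toward k when r > 0."""
    t = np.asarray(t_years, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    out = params.k / (1.0 + ((params.k - params.p0) / params.p0) * np.exp(-params.r * t))
    return float(out) if out.ndim == 0 else out


def fit_logistic_rate(p0: float, p_target: float, t: float, k: float = 1.0) -> float:
    """Rate r such that the logistic runs from p0 to p_target in t years."""
    if not 0 < p0 < p_target < k or t <= 0:
        raise ValueError("need 0 < p0 < p_target < k and t > 0")
    return float(np.log((p_target / (k - p_target)) / (p0 / (k - p0))) / t)


def fit_logistic_series(
    t: np.ndarray, percent: np.ndarray, k: float = 1.0
) -> LogisticParams:
    """Least-squares refit of (p0, r) from a percent-spread series."""

    def model(tt, p0, r):
        return 100.0 * k / (1.0 + ((k - p0) / p0) * np.exp(-r * tt))

    (p0, r), _ = curve_fit(
        model,
        np.asarray(t, dtype=float),
        np.asarray(percent, dtype=float),
        p0=(0.5, 0.1),
        bounds=((1e-4, 1e-4), (k - 1e-6, 2.0)),
        maxfev=10000,
    )
    return LogisticParams(p0=float(p0), r=float(r), k=k)


def _ordered_candidates(
    cand_iy: np.ndarray,
    cand_ix: np.ndarray,
    dist_km: np.ndarray,
    lats: np.ndarray,
    lons: np.ndarray,
) -> np.ndarray:
    """Candidate order: nearest first, ties broken lexicographically (lat, lon)."""
    return np.lexsort((lons[cand_ix], lats[cand_iy], dist_km))


def simulate_spread(
    seed_mask: np.ndarray,
    suitable: np.ndarray | Mapping[int, np.ndarray],
    grid: GridSpec,
    years: Sequence[int],
    params: LogisticParams | None = LogisticParams(),
    dispersal: DispersalConfig = DispersalConfig(),
) -> list[InfestationState]:
    """Deterministic constrained cellular spread.

    ``years[0]`` is the seed year: the returned first state is the seed
    itself and logistic time is measured from it.  Each later year the
    target infested count is ``round(P(t) · n_suitable)`` (all suitable
    cells when ``params`` is None); new cells are drawn from suitable,
    uninfested cells within ``annual_radius_km`` (great-circle) of the
    infested set at the start of the year, nearest first.  If the frontier
    cannot supply the target, what is reachable is filled and the shortfall
    logged.  Infestation is never revoked.
    """
    years = list(years)
    if not years:
        raise ValueError("empty year range")
    seed_mask = np.asarray(seed_mask, dtype=bool)

    def suit_at(year: int) -> np.ndarray:
        s = suitable[year] if isinstance(suitable, Mapping) else suitable
        return np.asarray(s, dtype=bool)

    if (seed_mask & ~suit_at(years[0])).any():
        raise ValueError("seed cells must all be suitable")

    lats, lons = grid.lats(), grid.lons()
    lon2d, lat2d = grid.mesh()
    year_first = np.where(seed_mask, years[0], 0).astype(int)
    states = [InfestationState(year_first.copy(), years[0])]

    for year in years[1:]:
        suit = suit_at(year)
        infested = year_first > 0
        n_suit = int(suit.sum())
        if params is None:
            target = n_suit
        else:
            target = int(round(logistic_fraction(year - years[0], params) * n_suit))
        need = target - int(infested.sum())
        if need > 0 and dispersal.annual_radius_km > 0 and infested.any():
            cand = suit & ~infested
            cand_iy, cand_ix = np.nonzero(cand)
            if cand_iy.size:
                src_iy, src_ix = np.nonzero(infested)
                tree = cKDTree(unit_vectors(lons[src_ix], lats[src_iy]))
                chord, _ = tree.query(unit_vectors(lons[cand_ix], lats[cand_iy]))
                dist_km = chord_to_arc_km(chord)
                within = dist_km <= dispersal.annual_radius_km
                cand_iy, cand_ix, dist_km = cand_iy[within], cand_ix[within], dist_km[within]
                order = _ordered_candidates(cand_iy, cand_ix, dist_km, lats, lons)
                take = order[:need]
                year_first[cand_iy[take], cand_ix[take]] = year
                if take.size < need:
                    logger.warning(
                        "spread %d: frontier exhausted, shortfall %d cells",
                        year,
                        need - take.size,
                    )
        elif need > 0:
            logger.warning("spread %d: no reachable frontier, shortfall %d cells", year, need)
        states.append(InfestationState(year_first.copy(), year))
    return states


#: Category codes for the affected-age classification.
CATEGORY_CODES = {"unaffected": 0, "newly": 1, "recently": 2, "longer": 3}


def affected_categories(state: InfestationState, horizon: int | None = None) -> np.ndarray:
    """Affected-age classes at a horizon: newly ≤5 y, recently 5–15 y, longer >15 y.

    Returns an integer raster with :data:`CATEGORY_CODES` values; every cell
    falls in exactly one class.
    """
    horizon = state.horizon if horizon is None else horizon
    yf = state.year_first
    if (yf > horizon).any():
        raise ValueError("state contains infestation years beyond the horizon")
    age = horizon - yf
    out = np.zeros(yf.shape, dtype=int)
    infested = yf > 0
    out[infested & (age < 5)] = CATEGORY_CODES["newly"]
    out[infested & (age >= 5) & (age < 15)] = CATEGORY_CODES["recently"]
    out[infested & (age >= 15)] = CATEGORY_CODES["longer"]
    return out


def spread_series(states: Sequence[InfestationState], suitable: np.ndarray):
    """Per-year infested percentage of suitable cells, as a DataFrame."""
    import pandas as pd

    suitable = np.asarray(suitable, dtype=bool)
    n_suit = int(suitable.sum())
    if n_suit == 0:
        raise ValueError("no suitable cells: spread percentage undefined")
    rows = []
    for st in states:
        n_inf = int((st.infested & suitable).sum())
        rows.append(
            {
                "year": st.horizon,
                "infested_cells": n_inf,
                "suitable_cells": n_suit,
                "spread_pct": 100.0 * n_inf / n_suit,
            }
        )
    return pd.DataFrame(rows)
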