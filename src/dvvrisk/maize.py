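"""Maize cultivated-area estimation, band classification, and projection.

The per-country estimate is the two-source-year average in million ha,
rounded half-up to one decimal and expressed in thousand ha (so Romania's
2.5 Mha average reports as 2500 k ha).  The continental projection is an
exponential curve anchored at 6,000 k ha in 2024 with rate ln(20/6)/30
per year, which reaches 20 million ha at 2054.
"""

from __future__ import annotations

import dataclasses
import math
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

__all__ = [
    "AreaBands",
    "MaizeGrowthCurve",
    "BAND_ORDER",
    "estimate_final_area",
    "band_of",
    "merged_band_of",
    "project_area",
    "area_table",
]

BAND_ORDER = ("small", "moderate", "large_medium", "very_large")


@dataclasses.dataclass(frozen=True)
class AreaBands:
    """Four-band partition of cultivated area (k ha), half-open at the cuts.

    small [0, 500) < moderate [500, 1000) < large_medium [1000, 2000] <
    very_large (2000, ∞).  The coarser three-band reporting scheme merges
    the top two bands into one "intensive" (>1000) class.
    """

    small_max: float = 500.0
    moderate_max: float = 1000.0
    large_max: float = 2000.0


@dataclasses.dataclass(frozen=True)
class MaizeGrowthCurve:
    """Continental expansion curve a(y) = a0 · e^{rate · (y − 2024)} (k ha)."""

    a0: float = 6000.0
    rate: float = math.log(20.0 / 6.0) / 30.0
    anchor_year: int = 2024
    kind: str = "exponential"  # or "linear"

    def __post_init__(self) -> None:
        if self.a0 <= 0:
            raise ValueError("a0 must be > 0")
        if self.kind not in ("exponential", "linear"):
            raise ValueError("kind must be 'exponential' or 'linear'")


def estimate_final_area(value_year1_mha: float, value_year2_mha: float) -> float:
    """Final area (k ha): two-year average in Mha, rounded half-up to 0.1, ×1000."""
    if value_year1_mha < 0 or value_year2_mha < 0:
        raise ValueError("area values must be non-negative")
    mean = (Decimal(str(value_year1_mha)) + Decimal(str(value_year2_mha))) / 2
    rounded = mean.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)
    return float(rounded * 1000)


def band_of(area_kha: float, bands: AreaBands = AreaBands()) -> str:
    """Four-band category of an area; cut points belong to the upper band."""
    if area_kha < 0:
        raise ValueError("area must be >= 0")
    if area_kha < bands.small_max:
        return "small"
    if area_kha < bands.moderate_max:
        return "moderate"
    if area_kha <= bands.large_max:
        return "large_medium"
    return "very_large"


def merged_band_of(area_kha: float, bands: AreaBands = AreaBands()) -> str:
    """Three-band reporting view: the two >1000 k ha bands merge to 'intensive'."""
    four = band_of(area_kha, bands)
    if four in ("large_medium", "very_large"):
        return "intensive"
    return {"moderate": "moderate", "small": "weak"}[four]


def project_area(year: int, curve: MaizeGrowthCurve = MaizeGrowthCurve()) -> float:
    """Projected continental maize area (k ha) for 2024 ≤ year ≤ 2074."""
    if not 2024 <= year <= 2074:
        raise ValueError(f"projection year must be in [2024, 2074], got {year}")
    t = year - curve.anchor_year
    if curve.kind == "linear":
        # endpoint-matched linear alternative
        end = curve.a0 * math.exp(curve.rate * 30)
        return curve.a0 + (end - curve.a0) * t / 30.0
    return curve.a0 * math.exp(curve.rate * t)


def area_table(fixture: pd.DataFrame, bands: AreaBands = AreaBands()) -> pd.DataFrame:
    """Apply the estimation formula and band rule to a two-year fixture."""
    out = fixture.copy()
    out["final_area_kha"] = [
        estimate_final_area(a, b) for a, b in zip(out["mha_y1"], out["mha_y2"])
    ]
    out["band"] = [band_of(a, bands) for a in out["final_area_kha"]]
    out["band_merged"] = [merged_band_of(a, bands) for a in out["final_area_kha"]]
    return out
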