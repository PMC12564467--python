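"""Regular lon/lat rasters and Esri ASCII grid I/O.

All rasters in the package live on a WGS84 lon/lat grid with cell-center
registration and half-open cell ownership ``[edge, edge + res)``.  Arrays are
indexed ``[lat, lon]`` (or ``[month, lat, lon]``) with latitude *ascending*
along its axis; the ASCII writer flips to the format's north-to-south row
order on the way out.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path

import numpy as np

__all__ = [
    "GridSpec",
    "MonthlyClimateGrid",
    "InvalidGridError",
    "AsciiGridParseError",
    "read_ascii_grid",
    "write_ascii_grid",
]

DEFAULT_NODATA = -9999.0


class InvalidGridError(ValueError):
    """Raised for inconsistent grid geometry (non-positive resolution, ...)."""


class AsciiGridParseError(ValueError):
    """Raised for malformed Esri ASCII grid files; carries the line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


@dataclasses.dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular lon/lat raster (degrees, cell-center registered).

    Defaults cover the European window used throughout the analysis:
    10°W–40°E, 35–70°N at 0.25°.
    """

    lon_min: float = -10.0
    lon_max: float = 40.0
    lat_min: float = 35.0
    lat_max: float = 70.0
    resolution: float = 0.25

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise InvalidGridError(f"resolution must be > 0, got {self.resolution}")
        if not (self.lon_min < self.lon_max and self.lat_min < self.lat_max):
            raise InvalidGridError("grid bounds must satisfy min < max on both axes")
        for span in ((self.lon_max - self.lon_min), (self.lat_max - self.lat_min)):
            n = span / self.resolution
            if abs(n - round(n)) > 1e-8:
                raise InvalidGridError(
                    f"span {span} is not an integer multiple of resolution {self.resolution}"
                )

    @property
    def nlon(self) -> int:
        return round((self.lon_max - self.lon_min) / self.resolution)

    @property
    def nlat(self) -> int:
        return round((self.lat_max - self.lat_min) / self.resolution)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nlat, self.nlon)

    def lons(self) -> np.ndarray:
        """Cell-center longitudes, ascending."""
        return self.lon_min + self.resolution * (np.arange(self.nlon) + 0.5)

    def lats(self) -> np.ndarray:
        """Cell-center latitudes, ascending (south to north)."""
        return self.lat_min + self.resolution * (np.arange(self.nlat) + 0.5)

    def mesh(self) -> tuple[np.ndarray, np.ndarray]:
        """(lon2d, lat2d) cell-center meshes with shape ``(nlat, nlon)``."""
        return np.meshgrid(self.lons(), self.lats())

    def contains(self, lon: float, lat: float) -> bool:
        return (
            self.lon_min <= lon < self.lon_max and self.lat_min <= lat < self.lat_max
        )

    def cell_index(self, lon: float, lat: float) -> tuple[int, int]:
        """(iy, ix) of the cell owning (lon, lat); half-open ownership.

        Raises ``ValueError`` for points outside the grid.
        """
        if not self.contains(lon, lat):
            raise ValueError(f"point ({lon}, {lat}) outside grid bounds")
        ix = int(math.floor((lon - self.lon_min) / self.resolution))
        iy = int(math.floor((lat - self.lat_min) / self.resolution))
        return iy, ix


@dataclasses.dataclass
class MonthlyClimateGrid:
    """Twelve monthly mean temperature layers (°C) on one :class:`GridSpec`.

    ``tmax`` (monthly mean daily maxima) is optional; where absent, consumers
    that need it approximate it as ``tmean + offset``.
    """

    grid: GridSpec
    tmean: np.ndarray  # (12, nlat, nlon)
    tmax: np.ndarray | None = None
    label: str = ""

    def __post_init__(self) -> None:
        expected = (12, self.grid.nlat, self.grid.nlon)
        if self.tmean.shape != expected:
            raise InvalidGridError(
                f"tmean shape {self.tmean.shape} != expected {expected}"
            )
        if self.tmax is not None and self.tmax.shape != expected:
            raise InvalidGridError(
                f"tmax shape {self.tmax.shape} != expected {expected}"
            )

    def month(self, m: int) -> np.ndarray:
        """Monthly mean layer for 1-based calendar month ``m``."""
        if not 1 <= m <= 12:
            raise ValueError(f"month must be in 1..12, got {m}")
        return self.tmean[m - 1]

    def shifted(self, delta: float) -> "MonthlyClimateGrid":
        """A copy with every layer shifted by ``delta`` °C."""
        return MonthlyClimateGrid(
            grid=self.grid,
            tmean=self.tmean + delta,
            tmax=None if self.tmax is None else self.tmax + delta,
            label=self.label,
        )


def write_ascii_grid(
    path: str | Path,
    values: np.ndarray,
    grid: GridSpec,
    nodata: float = DEFAULT_NODATA,
) -> None:
    """Write a single 2-D layer (lat ascending) as an Esri ASCII grid.

    NaN cells are written as ``nodata``.  Finite values are written with
    ``repr`` so the round-trip is bit-exact.
    """
    if values.shape != grid.shape:
        raise InvalidGridError(f"layer shape {values.shape} != grid {grid.shape}")
    out = np.where(np.isnan(values), nodata, values)
    lines = [
        f"ncols {grid.nlon}",
        f"nrows {grid.nlat}",
        f"xllcorner {grid.lon_min!r}",
        f"yllcorner {grid.lat_min!r}",
        f"cellsize {grid.resolution!r}",
        f"NODATA_value {nodata!r}",
    ]
    # rows north -> south
    for row in out[::-1]:
        lines.append(" ".join(repr(float(v)) for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, GridSpec, float]:
    """Read an Esri ASCII grid; returns (values lat-ascending, spec, nodata).

    Cells equal to the NODATA value come back as NaN.
    """
    text = Path(path).read_text().splitlines()
    header: dict[str, float] = {}
    keys = {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"}
    i = 0
    while i < len(text):
        parts = text[i].split()
        if len(parts) == 2 and parts[0].lower() in keys:
            try:
                header[parts[0].lower()] = float(parts[1])
            except ValueError:
                raise AsciiGridParseError(f"bad header value {parts[1]!r}", i + 1)
            i += 1
        else:
            break
    for required in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if required not in header:
            raise AsciiGridParseError(f"missing header key {required!r}", i + 1)
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    cell = header["cellsize"]
    nodata = header.get("nodata_value", DEFAULT_NODATA)
    rows = []
    for j, line in enumerate(text[i:], start=i + 1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != ncols:
            raise AsciiGridParseError(
                f"expected {ncols} values, found {len(parts)}", j
            )
        try:
            rows.append([float(p) for p in parts])
        except ValueError:
            raise AsciiGridParseError("non-numeric cell value", j)
    if len(rows) != nrows:
        raise AsciiGridParseError(
            f"expected {nrows} data rows, found {len(rows)}", len(text)
        )
    values = np.array(rows, dtype=float)[::-1]  # back to lat-ascending
    values[values == nodata] = np.nan
    spec = GridSpec(
        lon_min=header["xllcorner"],
        lon_max=header["xllcorner"] + ncols * cell,
        lat_min=header["yllcorner"],
        lat_max=header["yllcorner"] + nrows * cell,
        resolution=cell,
    )
    return values, spec, nodata
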