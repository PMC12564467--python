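"""Great-circle geometry on the WGS84 sphere (R = 6371 km)."""

from __future__ import annotations

import numpy as np
from shapely.geometry import Polygon

EARTH_RADIUS_KM = 6371.0

__all__ = [
    "EARTH_RADIUS_KM",
    "haversine_km",
    "unit_vectors",
    "chord_to_arc_km",
    "destination_point",
    "geodesic_circle",
    "polygon_area_km2",
]


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in km; accepts scalars or broadcastable arrays."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float)) for x in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def unit_vectors(lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
    """(n, 3) unit sphere coordinates for lon/lat in degrees."""
    lon = np.radians(np.asarray(lon, dtype=float))
    lat = np.radians(np.asarray(lat, dtype=float))
    return np.column_stack(
        (np.cos(lat) * np.cos(lon), np.cos(lat) * np.sin(lon), np.sin(lat))
    )


def chord_to_arc_km(chord: np.ndarray) -> np.ndarray:
    """Convert unit-sphere chord lengths (e.g. KD-tree distances) to arc km."""
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.clip(np.asarray(chord) / 2.0, 0.0, 1.0))


def destination_point(lon: float, lat: float, bearing_deg: float, distance_km: float) -> tuple[float, float]:
    """Point reached from (lon, lat) on the given initial bearing and distance."""
    delta = distance_km / EARTH_RADIUS_KM
    theta = np.radians(bearing_deg)
    phi1, lam1 = np.radians(lat), np.radians(lon)
    phi2 = np.arcsin(
        np.sin(phi1) * np.cos(delta) + np.cos(phi1) * np.sin(delta) * np.cos(theta)
    )
    lam2 = lam1 + np.arctan2(
        np.sin(theta) * np.sin(delta) * np.cos(phi1),
        np.cos(delta) - np.sin(phi1) * np.sin(phi2),
    )
    return float(np.degrees(lam2)), float(np.degrees(phi2))


def geodesic_circle(lon: float, lat: float, radius_km: float, n_points: int = 96) -> Polygon:
    """Small circle of given geodesic radius, as a lon/lat polygon."""
    if radius_km < 0:
        raise ValueError("radius must be >= 0")
    pts = [
        destination_point(lon, lat, 360.0 * i / n_points, radius_km)
        for i in range(n_points)
    ]
    pts.append(pts[0])
    return Polygon(pts)


def polygon_area_km2(poly: Polygon) -> float:
    """Area of a lon/lat polygon via a local sinusoidal (equal-area) projection."""
    lons, lats = np.asarray(poly.exterior.coords).T
    lon0 = lons.mean()
    k = np.pi / 180.0 * EARTH_RADIUS_KM
    x = (lons - lon0) * np.cos(np.radians(lats)) * k
    y = lats * k
    return float(Polygon(np.column_stack((x, y))).area)
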