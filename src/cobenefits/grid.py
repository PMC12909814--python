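"""Rectilinear latitude-longitude grids with spherical cell areas.

Conventions (shared by every gridded field in the package):

* grids are described by cell-*edge* arrays, latitude ascending,
  longitude ascending within [-180, 180];
* cell membership at edges is half-open: west and south edges inclusive,
  east and north exclusive, so adjacent cells never double-count;
* cell areas use the spherical-rectangle formula
  ``A = R^2 (sin(lat2) - sin(lat1)) * dlon`` with R the Earth radius in
  metres, so a grid spanning the whole sphere partitions ``4 pi R^2``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError

EARTH_RADIUS_M = 6.371e6


def _check_edges(edges: np.ndarray, name: str, lo: float, hi: float) -> np.ndarray:
    edges = np.asarray(edges, dtype=float)
    if edges.ndim != 1 or edges.size < 3:
        raise ConfigurationError(f"{name} edges need >= 3 values (>= 2 cells)")
    if not np.all(np.isfinite(edges)):
        raise ConfigurationError(f"{name} edges must be finite")
    if not np.all(np.diff(edges) > 0):
        raise ConfigurationError(f"{name} edges must be strictly ascending")
    if edges[0] < lo - 1e-9 or edges[-1] > hi + 1e-9:
        raise ConfigurationError(f"{name} edges must lie within [{lo}, {hi}]")
    return edges


@dataclass(frozen=True)
class Grid:
    """A rectilinear lat-lon grid defined by its cell edges (degrees)."""

    lat_edges: np.ndarray
    lon_edges: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "lat_edges", _check_edges(self.lat_edges, "lat", -90.0, 90.0)
        )
        object.__setattr__(
            self, "lon_edges", _check_edges(self.lon_edges, "lon", -180.0, 180.0)
        )

    @classmethod
    def regular(
        cls,
        n_lat: int,
        n_lon: int,
        lat_bounds: tuple[float, float] = (-90.0, 90.0),
        lon_bounds: tuple[float, float] = (-180.0, 180.0),
    ) -> "Grid":
        """Build a grid with ``n_lat`` x ``n_lon`` equally spaced cells."""
        if n_lat < 2 or n_lon < 2:
            raise ConfigurationError("need at least 2 cells along each axis")
        if lat_bounds[0] >= lat_bounds[1] or lon_bounds[0] >= lon_bounds[1]:
            raise ConfigurationError("degenerate lat/lon bounds")
        return cls(
            lat_edges=np.linspace(lat_bounds[0], lat_bounds[1], n_lat + 1),
            lon_edges=np.linspace(lon_bounds[0], lon_bounds[1], n_lon + 1),
        )

    # -- geometry -----------------------------------------------------------

    @property
    def n_lat(self) -> int:
        return self.lat_edges.size - 1

    @property
    def n_lon(self) -> int:
        return self.lon_edges.size - 1

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_lat, self.n_lon)

    @property
    def n_cells(self) -> int:
        return self.n_lat * self.n_lon

    @property
    def lat_centers(self) -> np.ndarray:
        return 0.5 * (self.lat_edges[:-1] + self.lat_edges[1:])

    @property
    def lon_centers(self) -> np.ndarray:
        return 0.5 * (self.lon_edges[:-1] + self.lon_edges[1:])

    def cell_areas(self) -> np.ndarray:
        """Cell areas in m^2, shape (n_lat, n_lon)."""
        sinlat = np.sin(np.deg2rad(self.lat_edges))
        band = EARTH_RADIUS_M**2 * np.diff(sinlat)  # per radian of longitude
        dlon = np.deg2rad(np.diff(self.lon_edges))
        return band[:, None] * dlon[None, :]

    def matches(self, other: "Grid") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.lat_edges, other.lat_edges)
            and np.allclose(self.lon_edges, other.lon_edges)
        )

    def great_circle_km(self, lat0: float, lon0: float) -> np.ndarray:
        """Haversine distance (km) from (lat0, lon0) to every cell center."""
        lat = np.deg2rad(self.lat_centers)[:, None]
        lon = np.deg2rad(self.lon_centers)[None, :]
        p0, l0 = np.deg2rad(lat0), np.deg2rad(lon0)
        a = (
            np.sin((lat - p0) / 2) ** 2
            + np.cos(lat) * np.cos(p0) * np.sin((lon - l0) / 2) ** 2
        )
        return 2 * (EARTH_RADIUS_M / 1e3) * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
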