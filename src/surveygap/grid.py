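"""Grid specification, point-to-cell assignment, cell geometry, time periods.

Occurrence records are aggregated into rectangular latitude/longitude grid
cells (default 0.1 deg x 0.1 deg) anchored so that cell edges fall on
multiples of the cell size.  A *survey* is the set of records falling in one
cell within one time period.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0088

#: tolerance used to snap coordinates sitting numerically on a cell edge
_EDGE_TOL = 1e-9


@dataclass(frozen=True)
class GridSpec:
    """A regular lon/lat grid of rectangular cells.

    Cells are half-open rectangles ``[edge, edge + cell_size)`` in both axes,
    closed on the lower (western / southern) edge, so a point on a shared
    edge lands in exactly one cell: the one on the greater side.

    Parameters
    ----------
    lon_min, lat_min, lon_max, lat_max
        Bounding box of the grid extent in decimal degrees (WGS84 assumed).
        The origin ``(lon_min, lat_min)`` anchors the cell edges.
    cell_size
        Cell edge length in degrees (square cells), default 0.1.
    mask
        Optional explicit set of cell ids constituting the study region
        (the *background* cells).  ``None`` means every cell in the extent.
    """

    lon_min: float = -180.0
    lat_min: float = -90.0
    lon_max: float = 180.0
    lat_max: float = 90.0
    cell_size: float = 0.1
    mask: frozenset[int] | None = field(default=None)

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.lon_max <= self.lon_min or self.lat_max <= self.lat_min:
            raise ValueError("extent must have positive width and height")
        if self.mask is not None:
            ids = np.asarray(sorted(self.mask), dtype=np.int64)
            if ids.size and (ids.min() < 0 or ids.max() >= self.n_cells):
                raise ValueError("mask contains cell ids outside the extent")

    @property
    def n_lon(self) -> int:
        return int(np.ceil((self.lon_max - self.lon_min) / self.cell_size - _EDGE_TOL))

    @property
    def n_lat(self) -> int:
        return int(np.ceil((self.lat_max - self.lat_min) / self.cell_size - _EDGE_TOL))

    @property
    def n_cells(self) -> int:
        return self.n_lon * self.n_lat

    def background_ids(self) -> np.ndarray:
        """Sorted array of background (study-region) cell ids."""
        if self.mask is None:
            return np.arange(self.n_cells, dtype=np.int64)
        return np.asarray(sorted(self.mask), dtype=np.int64)

    # -- indexing ----------------------------------------------------------

    def cell_index(self, lon, lat):
        """Map coordinates to integer column/row indices (vectorized).

        Points numerically on an edge (within 1e-9 cell widths) are snapped
        to the greater-side cell per the half-open convention.  Points outside
        the extent get index -1.
        """
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        ix = self._axis_index(lon, self.lon_min, self.n_lon)
        iy = self._axis_index(lat, self.lat_min, self.n_lat)
        return ix, iy

    def _axis_index(self, v: np.ndarray, v0: float, n: int) -> np.ndarray:
        t = (v - v0) / self.cell_size
        r = np.round(t)
        idx = np.where(np.abs(t - r) <= _EDGE_TOL, r, np.floor(t)).astype(np.int64)
        idx[(idx < 0) | (idx >= n)] = -1
        return idx

    def cell_id(self, ix, iy):
        """Row-major cell id ``iy * n_lon + ix``; -1 propagates."""
        ix = np.asarray(ix)
        iy = np.asarray(iy)
        out = iy * self.n_lon + ix
        return np.where((ix < 0) | (iy < 0), -1, out)

    def cell_id_of(self, lon, lat):
        ix, iy = self.cell_index(lon, lat)
        return self.cell_id(ix, iy)

    def cell_bounds(self, cell_id) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(lon_min, lat_min, lon_max, lat_max) of cells, vectorized."""
        cid = np.asarray(cell_id, dtype=np.int64)
        if np.any((cid < 0) | (cid >= self.n_cells)):
            raise ValueError("cell id outside grid")
        ix = cid % self.n_lon
        iy = cid // self.n_lon
        x0 = self.lon_min + ix * self.cell_size
        y0 = self.lat_min + iy * self.cell_size
        return x0, y0, x0 + self.cell_size, y0 + self.cell_size

    def cell_centers(self, cell_id) -> tuple[np.ndarray, np.ndarray]:
        x0, y0, x1, y1 = self.cell_bounds(cell_id)
        return (x0 + x1) / 2.0, (y0 + y1) / 2.0


def cell_geometry(cell_id: int, grid: GridSpec) -> dict:
    """Metric geometry of one cell on the WGS84 sphere.

    Returns bounds in degrees plus east-west width, north-south height (km)
    and area (km^2), using the spherical small-rectangle approximation
    ``width = dlon * (pi/180) * R * cos(center latitude)``.
    """
    x0, y0, x1, y1 = grid.cell_bounds(cell_id)
    lat_c = (float(y0) + float(y1)) / 2.0
    height_km = (float(y1) - float(y0)) * np.pi / 180.0 * EARTH_RADIUS_KM
    width_km = (float(x1) - float(x0)) * np.pi / 180.0 * EARTH_RADIUS_KM * np.cos(
        np.deg2rad(lat_c)
    )
    return {
        "lon_min": float(x0),
        "lat_min": float(y0),
        "lon_max": float(x1),
        "lat_max": float(y1),
        "width_km": width_km,
        "height_km": height_km,
        "area_km2": width_km * height_km,
    }


# -- time periods ----------------------------------------------------------

YEAR_MIN, YEAR_MAX = 1800, 2013


@dataclass(frozen=True)
class TimePeriodScheme:
    """Named inclusive year intervals defining survey time periods.

    Three built-ins cover the audit's designs: ``complete`` (1800-2013),
    ``contemporary`` (1990-2013) and ``intervals`` — ten 20-year bins plus a
    final truncated 14-year bin (2000-2013), eleven in total.
    """

    periods: tuple[tuple[str, int, int], ...]

    def __post_init__(self) -> None:
        for name, y0, y1 in self.periods:
            if y0 > y1:
                raise ValueError(f"period {name!r} has min year > max year")

    @property
    def names(self) -> list[str]:
        return [p[0] for p in self.periods]

    def interval(self, name: str) -> tuple[int, int]:
        for n, y0, y1 in self.periods:
            if n == name:
                return y0, y1
        raise ValueError(f"unknown period name: {name!r}")

    @classmethod
    def complete(cls) -> "TimePeriodScheme":
        return cls((("complete", YEAR_MIN, YEAR_MAX),))

    @classmethod
    def contemporary(cls) -> "TimePeriodScheme":
        return cls((("contemporary", 1990, YEAR_MAX),))

    @classmethod
    def intervals(cls) -> "TimePeriodScheme":
        periods = []
        y = YEAR_MIN
        while y < 2000:
            periods.append((f"{y}-{y + 19}", y, y + 19))
            y += 20
        periods.append(("2000-2013", 2000, YEAR_MAX))
        return cls(tuple(periods))

    @classmethod
    def standard(cls) -> "TimePeriodScheme":
        """complete + contemporary + the eleven intervals, in one scheme."""
        return cls(
            cls.complete().periods
            + cls.contemporary().periods
            + cls.intervals().periods
        )


def assign_cells(records: pd.DataFrame, grid: GridSpec) -> pd.DataFrame:
    """Assign each record to exactly one grid cell.

    Adds a ``cell_id`` column; records falling outside the extent or outside
    the grid's background mask are dropped, with the number dropped stored in
    ``result.attrs['n_dropped_outside']``.
    """
    out = records.copy()
    cid = grid.cell_id_of(out["longitude"].to_numpy(), out["latitude"].to_numpy())
    out["cell_id"] = cid
    keep = cid >= 0
    if grid.mask is not None:
        bg = grid.background_ids()
        keep &= np.isin(cid, bg)
    dropped = int((~keep).sum())
    out = out.loc[keep].reset_index(drop=True)
    out.attrs["n_dropped_outside"] = dropped
    return out
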