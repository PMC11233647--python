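"""Planar projection, great-circle distance and lightweight raster grids.

The study region (Svalbard to Franz Josef Land, 74-82 N) is far too close to
the pole for naive lon/lat arithmetic, so all planar work (interpolation,
gridding, kernel densities) happens in a local north-polar azimuthal
equidistant frame centred on the data. Distances reported in kilometres are
great-circle on a sphere of radius 6371 km.

Rasters are stored as ESRI ASCII grids (plain text, readable by any GIS),
with a small in-memory container shared by the bathymetry, ice and
time-in-area layers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

EARTH_RADIUS_KM = 6371.0


def great_circle_km(lon1, lat1, lon2, lat2):
    """Haversine distance in km; accepts scalars or numpy arrays."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(v, dtype=float))
                              for v in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


@dataclass(frozen=True)
class AzimuthalEquidistant:
    """Spherical azimuthal equidistant projection centred at (lon0, lat0).

    Forward maps degrees to metres; radial distances from the centre are
    exact great-circle distances, which keeps buffer radii and kernel
    bandwidths honest across the whole study area.
    """

    lon0: float
    lat0: float

    def forward(self, lon, lat):
        lam0 = math.radians(self.lon0)
        phi0 = math.radians(self.lat0)
        lam = np.radians(np.asarray(lon, dtype=float))
        phi = np.radians(np.asarray(lat, dtype=float))
        cos_c = (math.sin(phi0) * np.sin(phi)
                 + math.cos(phi0) * np.cos(phi) * np.cos(lam - lam0))
        cos_c = np.clip(cos_c, -1.0, 1.0)
        c = np.arccos(cos_c)
        # k -> 1 as c -> 0
        with np.errstate(invalid="ignore", divide="ignore"):
            k = np.where(c > 1e-12, c / np.sin(np.where(c > 1e-12, c, 1.0)), 1.0)
        R = EARTH_RADIUS_KM * 1000.0
        x = R * k * np.cos(phi) * np.sin(lam - lam0)
        y = R * k * (math.cos(phi0) * np.sin(phi)
                     - math.sin(phi0) * np.cos(phi) * np.cos(lam - lam0))
        return x, y

    def inverse(self, x, y):
        phi0 = math.radians(self.lat0)
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        R = EARTH_RADIUS_KM * 1000.0
        rho = np.hypot(x, y)
        c = rho / R
        safe_rho = np.where(rho > 1e-9, rho, 1.0)
        sin_c, cos_c = np.sin(c), np.cos(c)
        phi = np.arcsin(np.clip(cos_c * math.sin(phi0)
                                + (y * sin_c * math.cos(phi0)) / safe_rho, -1.0, 1.0))
        lam = math.radians(self.lon0) + np.arctan2(
            x * sin_c,
            safe_rho * math.cos(phi0) * cos_c - y * math.sin(phi0) * sin_c,
        )
        phi = np.where(rho > 1e-9, phi, phi0)
        lam = np.where(rho > 1e-9, lam, math.radians(self.lon0))
        lon = (np.degrees(lam) + 180.0) % 360.0 - 180.0
        return lon, np.degrees(phi)


def projection_for(lon, lat) -> AzimuthalEquidistant:
    """Projection centred on the centroid of a position cloud."""
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    # centroid on the unit sphere, then back to lon/lat
    lam, phi = np.radians(lon), np.radians(lat)
    v = np.array([np.cos(phi) * np.cos(lam), np.cos(phi) * np.sin(lam), np.sin(phi)])
    m = v.mean(axis=1)
    lon0 = math.degrees(math.atan2(m[1], m[0]))
    lat0 = math.degrees(math.atan2(m[2], math.hypot(m[0], m[1])))
    return AzimuthalEquidistant(lon0, lat0)


@dataclass(frozen=True)
class Grid:
    """Regular row-major grid of square cells, half-open in both axes.

    ``x0, y0`` is the lower-left corner; cell (row, col) covers
    ``[x0+col*cell, x0+(col+1)*cell) x [y0+row*cell, y0+(row+1)*cell)``.
    Units are metres for projected grids and degrees for lon/lat grids.
    """

    x0: float
    y0: float
    cell: float
    n_rows: int
    n_cols: int
    crs: str = "aeqd"

    @classmethod
    def from_bounds(cls, xmin, ymin, xmax, ymax, cell, crs="aeqd", pad_cells=1):
        x0 = xmin - pad_cells * cell
        y0 = ymin - pad_cells * cell
        n_cols = max(1, int(math.ceil((xmax - x0) / cell)) + pad_cells)
        n_rows = max(1, int(math.ceil((ymax - y0) / cell)) + pad_cells)
        return cls(x0, y0, cell, n_rows, n_cols, crs)

    @property
    def xmax(self) -> float:
        return self.x0 + self.n_cols * self.cell

    @property
    def ymax(self) -> float:
        return self.y0 + self.n_rows * self.cell

    def cell_index(self, x, y):
        col = np.floor((np.asarray(x, dtype=float) - self.x0) / self.cell).astype(int)
        row = np.floor((np.asarray(y, dtype=float) - self.y0) / self.cell).astype(int)
        return row, col

    def contains(self, x, y):
        row, col = self.cell_index(x, y)
        return (row >= 0) & (row < self.n_rows) & (col >= 0) & (col < self.n_cols)

    def cell_centers(self):
        xs = self.x0 + (np.arange(self.n_cols) + 0.5) * self.cell
        ys = self.y0 + (np.arange(self.n_rows) + 0.5) * self.cell
        return xs, ys

    @property
    def cell_area_km2(self) -> float:
        # only meaningful for metre grids
        return (self.cell / 1000.0) ** 2


@dataclass
class Raster:
    """A Grid plus a (n_rows, n_cols) value array; row 0 is the SOUTH row."""

    grid: Grid
    values: np.ndarray
    nodata: float = -9999.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.n_rows, self.grid.n_cols):
            raise ValueError(
                f"value array shape {self.values.shape} does not match grid "
                f"({self.grid.n_rows}, {self.grid.n_cols})"
            )

    def sample(self, x, y):
        """Nearest-cell lookup; NaN outside the grid or at nodata cells."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        row, col = self.grid.cell_index(x, y)
        ok = (row >= 0) & (row < self.grid.n_rows) & (col >= 0) & (col < self.grid.n_cols)
        out = np.full(np.broadcast(x, y).shape, np.nan)
        vals = self.values[row[ok], col[ok]]
        vals = np.where(vals == self.nodata, np.nan, vals)
        out[ok] = vals
        return out

    def write_ascii(self, path: str | Path) -> None:
        g = self.grid
        header = (
            f"ncols {g.n_cols}\nnrows {g.n_rows}\n"
            f"xllcorner {g.x0!r}\nyllcorner {g.y0!r}\n"
            f"cellsize {g.cell!r}\nNODATA_value {self.nodata!r}\n"
        )
        body = np.flipud(self.values)  # ascii grids are written north-down
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, body, fmt="%.8g")

    @classmethod
    def read_ascii(cls, path: str | Path, crs="aeqd") -> "Raster":
        header: dict[str, float] = {}
        with open(path) as fh:
            for _ in range(6):
                key, val = fh.readline().split()
                header[key.lower()] = float(val)
            body = np.loadtxt(fh)
        grid = Grid(
            header["xllcorner"], header["yllcorner"], header["cellsize"],
            int(header["nrows"]), int(header["ncols"]), crs,
        )
        body = np.atleast_2d(body)
        return cls(grid, np.flipud(body), nodata=header.get("nodata_value", -9999.0))
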