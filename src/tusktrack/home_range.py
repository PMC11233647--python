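"""Kernel utilization distributions, isopleths, overlap (PHR) and MCP centroids.

A season's utilization distribution (UD) is a bivariate Gaussian product
kernel density evaluated on a 500 m grid in the projected frame, with the
ad hoc bivariate reference bandwidth

    h_ref = 0.5 * (sd_x + sd_y) * n^(-1/6),

the convention of the standard home-range packages. Core areas are the 50%
isopleth (the smallest set of cells holding half the UD mass); general
ranges use 95%. Interannual site fidelity is the one-way overlap index

    PHR_{i,i+1}(level) = mass of the year-(i+1) UD inside the year-i
                         level-isopleth region,

which lies in [0, level] and is rescaled by 1/level for comparison across
levels. PHR is deliberately asymmetric: it asks whether next year's use
falls inside this year's range, not the converse.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import MultiPoint, box
from shapely.ops import unary_union

from .geo import Grid, Raster

DEFAULT_UD_CELL_M = 500.0
MIN_SEASON_HOURS = 30 * 24.0  # "at least one month" of within-season span


def href_bandwidth(x, y) -> float:
    """Reference bandwidth (metres) on projected coordinates."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 5:
        raise ValueError(f"need at least 5 positions for href (got {n})")
    h = 0.5 * (x.std(ddof=1) + y.std(ddof=1)) * n ** (-1.0 / 6.0)
    if h <= 0.0:
        raise ValueError("degenerate positions: reference bandwidth is zero")
    return float(h)


@dataclass
class UtilizationDistribution:
    grid: Grid
    mass: np.ndarray          # per-cell probability mass, sums to 1
    h: float                  # bandwidth (m)
    n: int                    # positions used
    season: str | None = None
    year: int | None = None


def kernel_ud(x, y, cell: float = DEFAULT_UD_CELL_M, h: float | None = None,
              grid: Grid | None = None, season: str | None = None,
              year: int | None = None) -> UtilizationDistribution:
    """Gaussian-kernel UD on a square grid; cell masses normalized to 1."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if h is None:
        h = href_bandwidth(x, y)
    if grid is None:
        pad = 3.5 * h
        grid = Grid.from_bounds(x.min() - pad, y.min() - pad,
                                x.max() + pad, y.max() + pad, cell, pad_cells=0)
    cx, cy = grid.cell_centers()
    dens = np.zeros((grid.n_rows, grid.n_cols))
    # separable kernel: outer product of per-axis Gaussian evaluations
    chunk = 2000
    for start in range(0, x.size, chunk):
        gx = np.exp(-0.5 * ((cx[None, :] - x[start:start + chunk, None]) / h) ** 2)
        gy = np.exp(-0.5 * ((cy[None, :] - y[start:start + chunk, None]) / h) ** 2)
        dens += gy.T @ gx
    total = dens.sum()
    if total <= 0:
        raise ValueError("all positions fall outside the UD grid")
    return UtilizationDistribution(grid, dens / total, float(h), int(x.size),
                                   season, year)


@dataclass
class IsoplethRegion:
    level: float
    grid: Grid
    mask: np.ndarray          # boolean cell membership
    area_km2: float

    def polygon(self):
        """Union of member cell squares as a shapely geometry (projected m)."""
        g = self.grid
        rows, cols = np.nonzero(self.mask)
        cells = [box(g.x0 + c * g.cell, g.y0 + r * g.cell,
                     g.x0 + (c + 1) * g.cell, g.y0 + (r + 1) * g.cell)
                 for r, c in zip(rows, cols)]
        return unary_union(cells)


def isopleth(ud: UtilizationDistribution, level: float) -> IsoplethRegion:
    """Smallest set of cells (by descending density) holding >= level mass."""
    flat = ud.mass.ravel()
    order = np.argsort(flat)[::-1]
    csum = np.cumsum(flat[order])
    k = int(np.searchsorted(csum, level - 1e-12)) + 1
    mask = np.zeros(flat.size, dtype=bool)
    mask[order[:k]] = True
    mask = mask.reshape(ud.mass.shape)
    return IsoplethRegion(level, ud.grid, mask,
                          float(k * ud.grid.cell_area_km2))


@dataclass
class OverlapResult:
    level: float
    raw: float                # in [0, level]
    rescaled: float           # raw / level, in [0, 1]


def phr_overlap(ud_next: UtilizationDistribution,
                region_prev: IsoplethRegion) -> OverlapResult:
    """Probability mass of ``ud_next`` inside last year's isopleth region.

    The two grids need not be aligned: each cell of ``ud_next`` contributes
    its mass if its centre falls in a member cell of the region (nearest-cell
    resampling on the region grid).
    """
    if ud_next.grid == region_prev.grid:
        raw = float(ud_next.mass[region_prev.mask].sum())
    else:
        cx, cy = ud_next.grid.cell_centers()
        X, Y = np.meshgrid(cx, cy)
        rows, cols = region_prev.grid.cell_index(X.ravel(), Y.ravel())
        ok = ((rows >= 0) & (rows < region_prev.grid.n_rows)
              & (cols >= 0) & (cols < region_prev.grid.n_cols))
        member = np.zeros(rows.size, dtype=bool)
        member[ok] = region_prev.mask[rows[ok], cols[ok]]
        raw = float(ud_next.mass.ravel()[member].sum())
    return OverlapResult(region_prev.level, raw, raw / region_prev.level)


def mcp_centroid(x, y, fraction: float = 0.5):
    """Centroid of the minimum convex polygon of the ``fraction`` of
    positions closest to their mean (distance-to-centroid peeling).

    Returns ``(cx, cy, hull)`` in the input (projected) coordinates.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 positions for an MCP")
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    mx, my = x.mean(), y.mean()
    d = np.hypot(x - mx, y - my)
    k = max(3, int(np.ceil(fraction * x.size)))
    keep = np.argsort(d, kind="stable")[:k]
    hull = MultiPoint(list(zip(x[keep], y[keep]))).convex_hull
    c = hull.centroid
    return float(c.x), float(c.y), hull


def core_area_size(ud: UtilizationDistribution, level: float = 0.5) -> float:
    """Area (km^2) of the level-isopleth region."""
    return isopleth(ud, level).area_km2


def season_long_enough(start, end, min_hours: float = MIN_SEASON_HOURS) -> bool:
    """Seasons shorter than about one month are excluded from UD estimation."""
    import pandas as pd

    return (pd.Timestamp(end) - pd.Timestamp(start)).total_seconds() / 3600.0 >= min_hours
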