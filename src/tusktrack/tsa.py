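"""Time Spent in Area: accumulate track time on an equal-area grid.

Each 3-h step of a regularized track is a straight planar segment; its
duration is apportioned across the grid cells it crosses in proportion to
the length of the segment inside each cell (a stationary step accrues wholly
to its cell). Gaps longer than the interpolation limit contribute nothing,
because regularization never places steps across them. Total accumulated
time is therefore conserved exactly: the raster sums to the within-segment
track duration.

For mapping, cell values are classified as percentile ranks of the
per-individual distribution of nonzero cells, and the 99th-percentile value
(in hours) is reported alongside.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .geo import Grid, Raster
from .preprocess import RegularTrack

DEFAULT_CELL_M = 3000.0


def grid_for_track(track: RegularTrack, cell: float = DEFAULT_CELL_M,
                   pad_cells: int = 2) -> Grid:
    d = track.data
    return Grid.from_bounds(d["x"].min(), d["y"].min(), d["x"].max(),
                            d["y"].max(), cell, crs="aeqd", pad_cells=pad_cells)


def time_spent_in_area(track: RegularTrack, grid: Grid | None = None,
                       cell: float = DEFAULT_CELL_M) -> Raster:
    """Accumulated hours per grid cell for one track."""
    if grid is None:
        grid = grid_for_track(track, cell)
    d = track.data
    inside = grid.contains(d["x"].to_numpy(), d["y"].to_numpy())
    if not inside.all():
        raise ValueError(
            f"track extends outside the analysis grid: track bounds "
            f"x [{d['x'].min():.0f}, {d['x'].max():.0f}], "
            f"y [{d['y'].min():.0f}, {d['y'].max():.0f}]; grid bounds "
            f"x [{grid.x0:.0f}, {grid.xmax:.0f}], y [{grid.y0:.0f}, {grid.ymax:.0f}]"
        )
    values = np.zeros((grid.n_rows, grid.n_cols))
    step_h = track.step_hours
    for _, seg in track.segments():
        x = seg["x"].to_numpy()
        y = seg["y"].to_numpy()
        th = (seg["timestamp"] - seg["timestamp"].iloc[0]).dt.total_seconds().to_numpy() / 3600.0
        for i in range(len(x) - 1):
            _accumulate_segment(values, grid, x[i], y[i], x[i + 1], y[i + 1],
                                th[i + 1] - th[i])
        if len(x) == 1:
            # a single-point segment has zero within-segment duration
            continue
    return Raster(grid, values)


def _accumulate_segment(values, grid: Grid, x0, y0, x1, y1, hours) -> None:
    if hours <= 0:
        return
    if x0 == x1 and y0 == y1:
        r, c = grid.cell_index(x0, y0)
        values[int(r), int(c)] += hours
        return
    # parameter values where the segment crosses cell edges
    ts = [0.0, 1.0]
    for (p0, p1, origin) in ((x0, x1, grid.x0), (y0, y1, grid.y0)):
        if p0 != p1:
            k0 = int(np.floor((min(p0, p1) - origin) / grid.cell)) + 1
            k1 = int(np.floor((max(p0, p1) - origin) / grid.cell))
            for k in range(k0, k1 + 1):
                t = (origin + k * grid.cell - p0) / (p1 - p0)
                if 0.0 < t < 1.0:
                    ts.append(t)
    ts = np.unique(ts)
    mids = 0.5 * (ts[:-1] + ts[1:])
    frac = np.diff(ts)
    rows, cols = grid.cell_index(x0 + mids * (x1 - x0), y0 + mids * (y1 - y0))
    np.add.at(values, (rows, cols), frac * hours)


def tsa_percentiles(raster: Raster):
    """Percentile classification of nonzero cells.

    Returns ``(percentile_raster, p99)`` where the percentile raster holds,
    for each visited cell, the percentile rank of its value among the
    individual's visited cells (NaN for unvisited cells), and ``p99`` is the
    99th percentile (linear interpolation) of the visited-cell hours.
    """
    vals = raster.values
    nz = vals > 0
    if not nz.any():
        raise ValueError("all-zero raster: no visited cells to classify")
    flat = vals[nz]
    ranks = stats.rankdata(flat, method="average") / flat.size * 100.0
    out = np.full_like(vals, np.nan)
    out[nz] = ranks
    p99 = float(np.percentile(flat, 99.0))
    return Raster(raster.grid, out), p99


def nonzero_cells_table(raster: Raster, percentiles: Raster | None = None):
    """(row, col, hours[, percentile]) records for CSV export."""
    import pandas as pd

    rows, cols = np.nonzero(raster.values > 0)
    out = pd.DataFrame({"row": rows, "col": cols,
                        "hours": raster.values[rows, cols]})
    if percentiles is not None:
        out["percentile"] = percentiles.values[rows, cols]
    return out
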