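"""Environmental annotation: day length, depth, sea-ice concentration.

Sea-ice concentration arrives as daily operational charts — polygons labelled
with one of six concentration classes. Each class is represented by its
mid-range value, charts are rasterized on a 0.05 x 0.05 degree grid, and
track positions are annotated by nearest-cell / nearest-date lookup (daily
files are sometimes missing).

The module also contains the pre-migration ice model: a linear mixed model
of daily mean ice concentration along the animal's positions during the two
weeks before the winter departure, comparing the window 14-8 days before
with 7-1 days before, with a random intercept per animal, an AR1 residual
correlation within each individual-year daily series, and a variance that
may differ between years. That covariance structure is fitted here directly
by restricted maximum likelihood.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from scipy import optimize, stats

from .geo import Grid, Raster

#: Operational chart classes and their mid-range concentrations (%).
ICE_CATEGORY_CONCENTRATION: dict[str, int] = {
    "Open water": 5,            # 0-1/10ths
    "Very Open Ice Drift": 25,  # 1-4/10ths
    "Open Ice Drift": 55,       # 4-7/10ths
    "Close Ice Drift": 80,      # 7-9/10ths
    "Very Close Ice Drift": 95, # 9-10/10ths
    "Fast Ice": 100,            # 10/10ths
}

ICE_VALUES = tuple(ICE_CATEGORY_CONCENTRATION.values())


def ice_category_to_concentration(category: str) -> int:
    try:
        return ICE_CATEGORY_CONCENTRATION[category]
    except KeyError:
        raise KeyError(
            f"unknown ice category {category!r}; expected one of "
            f"{list(ICE_CATEGORY_CONCENTRATION)}"
        ) from None


# --------------------------------------------------------------------------
# day length
# --------------------------------------------------------------------------

def daylight_hours(lat, lon, date) -> np.ndarray | float:
    """Day length in hours from the sunrise equation.

    Uses the standard solar-position series for the declination and a sun
    altitude of -0.833 degrees at rise/set (atmospheric refraction plus solar
    semidiameter). Returns 24 during polar day and 0 during polar night.
    ``lon`` shifts solar noon, not day length, and is accepted for interface
    symmetry with the other per-position extractors.
    """
    lat = np.asarray(lat, dtype=float)
    if np.isscalar(date) or isinstance(date, (pd.Timestamp, str)):
        doy = pd.Timestamp(date).dayofyear
    else:
        doy = pd.DatetimeIndex(np.asarray(date)).dayofyear.to_numpy()
    g = 2.0 * np.pi / 365.0 * (np.asarray(doy, dtype=float) - 1.0)
    decl = (0.006918 - 0.399912 * np.cos(g) + 0.070257 * np.sin(g)
            - 0.006758 * np.cos(2 * g) + 0.000907 * np.sin(2 * g)
            - 0.002697 * np.cos(3 * g) + 0.00148 * np.sin(3 * g))
    phi = np.radians(lat)
    h0 = math.radians(-0.833)
    cos_omega = (np.sin(h0) - np.sin(phi) * np.sin(decl)) / (
        np.cos(phi) * np.cos(decl))
    hours = np.where(cos_omega <= -1.0, 24.0,
                     np.where(cos_omega >= 1.0, 0.0,
                              2.0 * np.degrees(np.arccos(np.clip(cos_omega, -1, 1)))
                              / 15.0))
    return float(hours) if hours.ndim == 0 else hours


# --------------------------------------------------------------------------
# ice rasterization and lookup
# --------------------------------------------------------------------------

def rasterize_ice(chart, cell_deg: float = 0.05, bounds=None) -> Raster:
    """Rasterize one chart: each cell takes the category of the polygon
    containing its centre; cells outside all polygons are missing (NaN)."""
    polys = chart.polygons
    if bounds is None:
        xs, ys = [], []
        for poly, _ in polys:
            b = poly.bounds
            xs += [b[0], b[2]]
            ys += [b[1], b[3]]
        if not xs:
            raise ValueError("chart has no polygons and no bounds were given")
        bounds = (min(xs), min(ys), max(xs), max(ys))
    grid = Grid.from_bounds(bounds[0], bounds[1], bounds[2], bounds[3],
                            cell_deg, crs="lonlat", pad_cells=0)
    cx, cy = grid.cell_centers()
    X, Y = np.meshgrid(cx, cy)
    values = np.full((grid.n_rows, grid.n_cols), np.nan)
    for poly, cat in polys:
        if not poly.is_valid:
            warnings.warn(f"skipping invalid ice polygon (category {cat!r})")
            continue
        conc = float(ice_category_to_concentration(cat))
        unset = np.isnan(values)
        if not unset.any():
            break
        inside = shapely.contains_xy(poly, X[unset], Y[unset])
        idx = np.flatnonzero(unset.ravel())[inside]
        values.ravel()[idx] = conc
    out = Raster(grid, values)
    out.values = values  # keep NaN (not nodata sentinel) in memory
    return out


@dataclass
class IceChartSeries:
    """A dated stack of daily charts queried on a fixed 0.05-degree lattice.

    Sampling snaps each query position to the centre of its lattice cell and
    asks which polygon contains that centre — exactly the value the
    rasterized chart would hold in that cell, without materialising rasters
    for thousands of chart days.
    """

    charts: list
    cell_deg: float = 0.05
    lon0: float = 0.0
    lat0: float = 0.0

    @classmethod
    def from_charts(cls, charts, cell_deg: float = 0.05):
        charts = sorted(charts, key=lambda c: pd.Timestamp(c.date))
        return cls(charts, cell_deg)

    def nearest(self, date, max_days: float = 7.0):
        """Chart closest in time to ``date`` (ties go to the earlier chart);
        None if nothing lies within ``max_days``."""
        if not self.charts:
            return None
        date = pd.Timestamp(date).normalize()
        deltas = np.array([(pd.Timestamp(c.date) - date).total_seconds()
                           for c in self.charts])
        absd = np.abs(deltas)
        best = int(np.lexsort((deltas, absd))[0])  # tie -> earlier chart
        if absd[best] > max_days * 86400.0:
            return None
        return self.charts[best]

    def _snap(self, lon, lat):
        c = self.cell_deg
        lon = (np.floor((np.asarray(lon, float) - self.lon0) / c) + 0.5) * c + self.lon0
        lat = (np.floor((np.asarray(lat, float) - self.lat0) / c) + 0.5) * c + self.lat0
        return lon, lat

    def sample(self, date, lon, lat, max_days: float = 7.0) -> np.ndarray:
        chart = self.nearest(date, max_days)
        lon = np.atleast_1d(np.asarray(lon, float))
        out = np.full(lon.shape, np.nan)
        if chart is None:
            return out
        slon, slat = self._snap(lon, lat)
        for poly, cat in chart.polygons:
            if not poly.is_valid:
                continue
            unset = np.isnan(out)
            if not unset.any():
                break
            inside = shapely.contains_xy(poly, slon[unset], slat[unset])
            idx = np.flatnonzero(unset)[inside]
            out[idx] = float(ice_category_to_concentration(cat))
        return out


def ice_at_positions(timestamps, lon, lat, series: IceChartSeries,
                     max_days: float = 7.0) -> np.ndarray:
    """Per-position ice concentration (%), nearest cell and nearest date."""
    timestamps = pd.to_datetime(pd.Series(timestamps))
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    out = np.full(len(timestamps), np.nan)
    days = timestamps.dt.normalize()
    missing_warned = 0
    for day, idx in days.groupby(days.to_numpy()).groups.items():
        ii = np.asarray(idx)
        vals = series.sample(day, lon[ii], lat[ii], max_days)
        if np.isnan(vals).all() and series.nearest(day, max_days) is None:
            missing_warned += 1
        out[ii] = vals
    if missing_warned:
        warnings.warn(
            f"no ice chart within {max_days} days for {missing_warned} track days")
    return out


def daily_core_ice(region_lon, region_lat, date, series: IceChartSeries,
                   max_days: float = 7.0):
    """Mean and (min, max) ice concentration over a core-area point set."""
    vals = series.sample(date, np.asarray(region_lon, float),
                         np.asarray(region_lat, float), max_days)
    vals = vals[~np.isnan(vals)]
    if len(vals) == 0:
        return np.nan, (np.nan, np.nan)
    return float(vals.mean()), (float(vals.min()), float(vals.max()))


def depth_at_positions(lon, lat, bathymetry: Raster) -> np.ndarray:
    """Nearest-cell water depth (m, positive down); NaN off-raster or on land
    (cells with non-positive depth under the positive-down convention)."""
    d = bathymetry.sample(np.asarray(lon, float), np.asarray(lat, float))
    return np.where(d <= 0.0, np.nan, d)


# --------------------------------------------------------------------------
# pre-migration windows and mixed model
# --------------------------------------------------------------------------

def premigration_windows(track_ice: pd.DataFrame, departure) -> pd.DataFrame:
    """Daily mean ice along the track for days -14..-1 before departure.

    ``track_ice`` needs columns ``timestamp`` and ``ice_pct``. Day -k covers
    [departure - k days, departure - (k-1) days). Days -14..-8 form period
    "A" (two weeks before), days -7..-1 period "B" (the week before).
    """
    departure = pd.Timestamp(departure)
    t = pd.to_datetime(track_ice["timestamp"])
    day_index = np.floor((t - departure).dt.total_seconds() / 86400.0)
    sel = (day_index >= -14) & (day_index <= -1)
    if not sel.any():
        raise ValueError("no positions in the 14 days before departure")
    df = pd.DataFrame({"day": day_index[sel].astype(int),
                       "ice_pct": track_ice.loc[sel, "ice_pct"].to_numpy()})
    daily = df.groupby("day", as_index=False)["ice_pct"].mean()
    daily["period"] = np.where(daily["day"] <= -8, "A", "B")
    return daily


@dataclass
class PreMigrationModelFit:
    """REML fit of daily pre-migration ice concentration.

    Fixed effects: intercept, year (factor, first year reference), period
    (B - A contrast). Random intercept per animal; residuals AR1-correlated
    on day lag within each individual-year series with a per-year variance
    multiplier.
    """

    coefficients: pd.DataFrame   # Predictor, Value, SE, df, t, p
    sigma: float
    sigma_id: float
    ar1: float
    year_weights: dict
    transform: str
    loglik: float
    converged: bool
    n_obs: int

    @property
    def period_p_value(self) -> float:
        row = self.coefficients[self.coefficients["Predictor"] == "Period"]
        return float(row["p"].iloc[0])


def _build_design(df: pd.DataFrame):
    years = sorted(df["year"].unique())
    cols = ["Intercept"]
    X = [np.ones(len(df))]
    for y in years[1:]:
        X.append((df["year"] == y).to_numpy(float))
        cols.append(f"Year {y}")
    X.append((df["period"] == "B").to_numpy(float))
    cols.append("Period")
    return np.column_stack(X), cols, years


def fit_premigration_model(windows: pd.DataFrame, transform: str = "none",
                           ) -> PreMigrationModelFit:
    """Fit the pre-migration ice mixed model by REML.

    ``windows`` needs columns id, year, day, period ("A"/"B"), ice_pct with
    one row per animal-year-day. ``transform="arcsine_sqrt"`` models
    arcsin(sqrt(p)) of the concentration fraction (used for the northern
    group, where concentrations are small and skewed); ``"none"`` models the
    raw percentage.
    """
    df = windows.copy()
    if df["id"].nunique() < 2:
        raise ValueError("need at least 2 individuals")
    if transform == "arcsine_sqrt":
        df["y"] = np.arcsin(np.sqrt(np.clip(df["ice_pct"] / 100.0, 0.0, 1.0)))
    elif transform == "none":
        df["y"] = df["ice_pct"].astype(float)
    else:
        raise ValueError(f"unknown transform {transform!r}")
    df = df.sort_values(["id", "year", "day"]).reset_index(drop=True)

    X, names, years = _build_design(df)
    y = df["y"].to_numpy()
    n, p = X.shape
    multi_year = len(years) > 1
    year_idx = {yr: k for k, yr in enumerate(years)}

    # contiguous per-individual blocks; per series: local slice, year, lags
    blocks = []
    start = 0
    for _, g in df.groupby("id", sort=True):
        ni = len(g)
        series = []
        s0 = 0
        for yr, gy in g.groupby("year"):
            days = gy["day"].to_numpy(float)
            lag = np.abs(days[:, None] - days[None, :])
            series.append((slice(s0, s0 + len(gy)), year_idx[yr], lag))
            s0 += len(gy)
        blocks.append((slice(start, start + ni), series))
        start += ni

    # unit-scale covariance W (V = sigma^2 W); sigma profiled analytically
    def unpack(theta):
        phi = math.tanh(theta[0])
        r_id = math.exp(theta[1])            # sigma_id / sigma
        w = np.ones(len(years))
        if multi_year:
            w[1:] = np.exp(theta[2:2 + len(years) - 1])
        return phi, r_id, w

    def decompose(theta):
        phi, r_id, w = unpack(theta)
        XtWX = np.zeros((p, p))
        XtWy = np.zeros(p)
        logdet = 0.0
        parts = []
        for rows, series in blocks:
            ni = rows.stop - rows.start
            W = np.full((ni, ni), r_id ** 2)
            for sl, yk, lag in series:
                W[sl, sl] += w[yk] ** 2 * phi ** lag
            L = np.linalg.cholesky(W)
            logdet += 2.0 * np.log(np.diag(L)).sum()
            A = np.linalg.solve(L, np.column_stack([X[rows], y[rows]]))
            Ax, Ay = A[:, :p], A[:, p]
            XtWX += Ax.T @ Ax
            XtWy += Ax.T @ Ay
            parts.append((Ax, Ay))
        return logdet, XtWX, XtWy, parts

    def neg_reml(theta):
        try:
            logdet, XtWX, XtWy, parts = decompose(theta)
        except np.linalg.LinAlgError:
            return 1e10
        sign, ld_xx = np.linalg.slogdet(XtWX)
        if sign <= 0:
            return 1e10
        beta = np.linalg.solve(XtWX, XtWy)
        rss = sum(float((Ay - Ax @ beta) @ (Ay - Ax @ beta)) for Ax, Ay in parts)
        if rss <= 0:
            return 1e10
        sigma2 = rss / (n - p)
        return 0.5 * (logdet + ld_xx + (n - p) * (math.log(sigma2) + 1.0)
                      + (n - p) * math.log(2 * math.pi))

    theta0 = np.concatenate([[0.2, math.log(0.5)],
                             np.zeros(len(years) - 1 if multi_year else 0)])
    res = optimize.minimize(neg_reml, theta0, method="Nelder-Mead",
                            options={"maxiter": 2000, "xatol": 1e-4,
                                     "fatol": 1e-7})
    phi, r_id, w = unpack(res.x)

    # Wald table at the optimum
    logdet, XtWX, XtWy, parts = decompose(res.x)
    beta = np.linalg.solve(XtWX, XtWy)
    rss = sum(float((Ay - Ax @ beta) @ (Ay - Ax @ beta)) for Ax, Ay in parts)
    sigma2 = rss / (n - p)
    sigma = math.sqrt(sigma2)
    sigma_id = r_id * sigma
    cov = sigma2 * np.linalg.inv(XtWX)
    se = np.sqrt(np.diag(cov))
    df_resid = n - p
    tvals = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df_resid)
    table = pd.DataFrame({"Predictor": names, "Value": beta, "SE": se,
                          "df": df_resid, "t": tvals, "p": pvals})
    return PreMigrationModelFit(
        coefficients=table, sigma=sigma, sigma_id=sigma_id, ar1=phi,
        year_weights={yr: float(v) for yr, v in zip(years, w)},
        transform=transform, loglik=-res.fun, converged=bool(res.success),
        n_obs=n,
    )
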