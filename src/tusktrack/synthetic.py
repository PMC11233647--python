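"""Synthetic multi-year pinniped telemetry with known ground truth.

Real tusk-mounted GPS loggers attempt one fix per hour, succeed only when the
antenna is dry, and are downloaded opportunistically — producing tracks with
25-66 % failed attempts, frequent short gaps and occasional very long ones.
The animals themselves alternate between two seasonal ranges a few hundred
kilometres apart, connected by directed migrations of days to weeks, with
short (<14 day) "scouting" excursions to the winter area beforehand.

This module generates such data from an explicit latent model so that every
downstream estimator (regularization, phenology segmentation, utilization
distributions, move persistence) can be scored against truth:

* movement: a first-difference correlated random walk whose persistence
  parameter gamma switches between a resident and a transit level by
  behavioural phase — the generative dual of the move-persistence estimator;
* sampling: hourly attempts gated by a two-state (haul-out / at-sea) Markov
  chain; at-sea attempts fail with a probability calibrated so the *net*
  failure fraction equals ``fix_fail_prob``;
* environment: a seasonally varying, latitude-graded categorical ice field
  and a deterministic shelf-slope bathymetry.

All generators are deterministic functions of (inputs, seed).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import Polygon, mapping, shape

from .geo import AzimuthalEquidistant, Grid, Raster, great_circle_km
from .environment import ICE_CATEGORY_CONCENTRATION

STEP_HOURS = 3
STEPS_PER_DAY = 24 // STEP_HOURS

FIX_COLUMNS = ["id", "timestamp", "lon", "lat", "fix_ok"]

SEASON_SUMMER = "summer"
SEASON_WINTER = "winter"
SEASON_MIGRATION = "migration"
SEASON_SCOUTING = "scouting"


# --------------------------------------------------------------------------
# scenario
# --------------------------------------------------------------------------

@dataclass
class IndividualScenario:
    """Everything needed to simulate one animal's multi-year track."""

    id: str
    summer_center: tuple[float, float]          # (lon, lat)
    winter_center: tuple[float, float]
    start_date: str = "2015-08-12"
    n_years: int = 2
    duration_days: float | None = None          # truncate track; default n_years*365
    migration_depart_doy: int | None = 325      # day-of-year leaving summer range
                                                # (None: non-migratory animal)
    migration_return_doy: int = 110             # day-of-year leaving winter range
    migration_duration_days: float = 10.0
    scouting: list[tuple[int, float]] = field(default_factory=list)  # (start_doy, days)
    persistence_resident: float = 0.30
    persistence_transit: float = 0.90
    step_sd_km: float = 1.3                     # CRW innovation SD per 3-h step
    home_attraction: float = 0.12               # fraction of offset recovered per step
    fix_fail_prob: float = 0.45                 # net fraction of failed hourly attempts
    gps_noise_m: float = 30.0
    long_gaps: list[tuple[float, float]] = field(default_factory=list)  # (start_h, dur_h)
    haulout_stationary: float = 0.2             # long-run fraction of hours hauled out
    haulout_mean_bout_h: float = 3.0
    haulout_fail_factor: float = 0.5            # hauled-out failure rate relative to net
    separation_range_km: tuple[float, float] = (170.0, 430.0)

    def validate(self) -> None:
        sep = great_circle_km(*self.summer_center, *self.winter_center)
        if (self.migration_depart_doy is not None) and sep < 1e-6:
            raise ValueError(
                f"scenario {self.id}: summer and winter centers coincide but a "
                "migration is requested"
            )
        lo, hi = self.separation_range_km
        if not (lo <= sep <= hi):
            raise ValueError(
                f"scenario {self.id}: center separation {sep:.1f} km outside "
                f"configured range [{lo}, {hi}] km"
            )
        if self.persistence_transit <= self.persistence_resident:
            raise ValueError("persistence_transit must exceed persistence_resident")
        for g in (self.persistence_resident, self.persistence_transit):
            if not 0.0 < g < 1.0:
                raise ValueError("persistence parameters must lie in (0, 1)")
        if not 0.0 <= self.fix_fail_prob <= 1.0:
            raise ValueError("fix_fail_prob must lie in [0, 1]")
        for _, dur in self.scouting:
            if dur >= 14.0:
                raise ValueError("scouting trips must be shorter than 14 days")
        if self.n_years < 1:
            raise ValueError("n_years must be >= 1")


@dataclass
class SyntheticTruth:
    """Latent record of one simulated track.

    ``steps`` has one row per 3-h latent step: timestamp, lon, lat, projected
    x/y (m), behavioural season label and the true persistence gamma.
    ``events`` has one row per migration leg: direction, the latent phase
    switch (``depart``/``arrive``) and the core-area buffer crossings
    (``depart_core``/``arrive_core`` — the quantities a buffer-based
    migration detector estimates). ``path_length_km`` is the summed latent
    step length.
    """

    id: str
    steps: pd.DataFrame
    events: pd.DataFrame
    path_length_km: float
    projection: AzimuthalEquidistant

    def recompute_path_length(self) -> float:
        dx = np.diff(self.steps["x"].to_numpy()) / 1000.0
        dy = np.diff(self.steps["y"].to_numpy()) / 1000.0
        return float(np.hypot(dx, dy).sum())

    def yearly_path_lengths(self) -> pd.Series:
        t = self.steps["timestamp"]
        day = (t - t.iloc[0]).dt.total_seconds() / 86400.0
        year = np.minimum((day // 365).astype(int), int(day.iloc[-1] // 365))
        seg = np.hypot(np.diff(self.steps["x"]), np.diff(self.steps["y"])) / 1000.0
        return pd.Series(seg).groupby(year.to_numpy()[1:]).sum()


# --------------------------------------------------------------------------
# track simulation
# --------------------------------------------------------------------------

def _phase_schedule(scn: IndividualScenario, n_steps: int) -> list[tuple[int, str]]:
    """Scheduled phase-change triggers as (step_index, kind) sorted by step.

    kinds: 'depart' (summer->winter migration), 'return' (winter->summer),
    'scout' (begin scouting trip).
    """
    start = pd.Timestamp(scn.start_date)
    start_doy = start.dayofyear
    events: list[tuple[int, str]] = []
    for y in range(scn.n_years):
        base_day = y * 365
        if scn.migration_depart_doy is None:
            continue
        depart_day = base_day + (scn.migration_depart_doy - start_doy) % 365
        return_day = depart_day + (scn.migration_return_doy - scn.migration_depart_doy) % 365
        for s_doy, s_dur in scn.scouting:
            s_day = base_day + (s_doy - start_doy) % 365
            if s_day + s_dur < depart_day:  # must finish before true departure
                events.append((int(s_day * STEPS_PER_DAY), f"scout:{s_dur}"))
        events.append((int(depart_day * STEPS_PER_DAY), "depart"))
        events.append((int(return_day * STEPS_PER_DAY), "return"))
    return sorted([(s, k) for s, k in events if s < n_steps])


def simulate_track(scenario: IndividualScenario, seed: int):
    """Simulate one track; returns ``(fixes, truth)``.

    ``fixes`` is a DataFrame of hourly *attempts* (id, timestamp, lon, lat,
    fix_ok) where failed attempts carry a timestamp only; ``truth`` is the
    :class:`SyntheticTruth` latent record.
    """
    scn = scenario
    scn.validate()
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    proj = AzimuthalEquidistant(
        0.5 * (scn.summer_center[0] + scn.winter_center[0]),
        0.5 * (scn.summer_center[1] + scn.winter_center[1]),
    )
    sx, sy = proj.forward(*scn.summer_center)
    wx, wy = proj.forward(*scn.winter_center)
    centers = {SEASON_SUMMER: np.array([sx, sy]) / 1000.0,
               SEASON_WINTER: np.array([wx, wy]) / 1000.0}
    sep_km = float(np.hypot(*(centers[SEASON_WINTER] - centers[SEASON_SUMMER])))

    duration_days = scn.duration_days if scn.duration_days is not None else scn.n_years * 365
    n_steps = int(round(duration_days * STEPS_PER_DAY)) + 1
    schedule = _phase_schedule(scn, n_steps)
    sched_i = 0

    mig_speed = sep_km / max(scn.migration_duration_days * STEPS_PER_DAY, 1)  # km / 3 h

    pos = np.empty((n_steps, 2))
    gamma = np.empty(n_steps)
    label = np.empty(n_steps, dtype=object)
    pos[0] = centers[SEASON_SUMMER]
    vel = np.zeros(2)

    phase = SEASON_SUMMER            # current behavioural phase
    leg_target = None                # transit destination (km coords)
    leg_speed = 0.0
    leg_kind = None                  # 'migration' | 'scout_out' | 'scout_back'
    scout_stay_until = -1
    events: list[dict] = []
    current_event: dict | None = None
    arrive_radius_km = 6.0

    start = pd.Timestamp(scn.start_date)
    times = start + pd.to_timedelta(np.arange(n_steps) * STEP_HOURS, unit="h")

    for t in range(n_steps):
        # scheduled triggers
        while sched_i < len(schedule) and schedule[sched_i][0] <= t:
            step_i, kind = schedule[sched_i]
            sched_i += 1
            if kind == "depart" and phase == SEASON_SUMMER:
                phase, leg_kind = SEASON_MIGRATION, "migration"
                leg_target, leg_speed = centers[SEASON_WINTER], mig_speed
                current_event = {"direction": "to-winter", "depart": times[t]}
            elif kind == "return" and phase == SEASON_WINTER:
                phase, leg_kind = SEASON_MIGRATION, "migration"
                leg_target, leg_speed = centers[SEASON_SUMMER], mig_speed
                current_event = {"direction": "to-summer", "depart": times[t]}
            elif kind.startswith("scout") and phase == SEASON_SUMMER:
                s_dur = float(kind.split(":")[1])
                phase, leg_kind = SEASON_SCOUTING, "scout_out"
                # out + stay + back must fit inside s_dur days
                travel_steps = max(1, int(0.4 * s_dur * STEPS_PER_DAY))
                leg_target = centers[SEASON_WINTER]
                scout_speed = sep_km / travel_steps
                leg_speed = scout_speed
                scout_stay_until = t + int(0.9 * s_dur * STEPS_PER_DAY)

        # proximity-triggered transitions
        if leg_target is not None and np.hypot(*(pos[t] - leg_target)) < arrive_radius_km:
            if leg_kind == "migration":
                dest = (SEASON_WINTER
                        if current_event["direction"] == "to-winter" else SEASON_SUMMER)
                current_event["arrive"] = times[t]
                events.append(current_event)
                current_event = None
                phase, leg_target, leg_kind = dest, None, None
            elif leg_kind == "scout_out":
                # linger near the winter area until the scheduled turnaround
                leg_kind, leg_speed = "scout_hold", 0.0
            elif leg_kind == "scout_back":
                phase, leg_target, leg_kind = SEASON_SUMMER, None, None
        if leg_kind in ("scout_out", "scout_hold") and t >= scout_stay_until:
            leg_kind = "scout_back"
            leg_target = centers[SEASON_SUMMER]
            leg_speed = scout_speed

        in_transit = phase in (SEASON_MIGRATION, SEASON_SCOUTING) and leg_speed > 0.0
        g = scn.persistence_transit if in_transit else scn.persistence_resident
        gamma[t] = g
        label[t] = phase

        if t + 1 < n_steps:
            if in_transit:
                offset = leg_target - pos[t]
                dist = np.hypot(*offset)
                drift = offset / max(dist, 1e-9) * min(leg_speed, dist)
                sd = scn.step_sd_km * 0.6
            else:
                center = centers.get(phase, centers[SEASON_SUMMER])
                if phase == SEASON_SCOUTING:          # lingering at winter area
                    center = centers[SEASON_WINTER]
                drift = scn.home_attraction * (center - pos[t])
                dn = np.hypot(*drift)
                if dn > 4.0:
                    drift = drift / dn * 4.0
                sd = scn.step_sd_km
            vel = g * vel + (1.0 - g) * drift + sd * math.sqrt(1.0 - g * g) * rng.standard_normal(2)
            speed = np.hypot(*vel)
            vmax_step = 2.0 * 3.6 * STEP_HOURS * 0.95   # 2 m/s in km per 3 h, with margin
            if speed > vmax_step:
                vel = vel / speed * vmax_step
            pos[t + 1] = pos[t] + vel

    if current_event is not None:   # truncated mid-migration
        current_event["arrive"] = pd.NaT
        events.append(current_event)

    # core-area exit/entry times: the latent analogue of the buffer-based
    # migration definition (last step within core_radius_km of the origin
    # centre, first step within it of the destination centre)
    core_radius_km = 15.0
    for ev in events:
        origin = (SEASON_SUMMER if ev["direction"] == "to-winter"
                  else SEASON_WINTER)
        dest = SEASON_WINTER if origin == SEASON_SUMMER else SEASON_SUMMER
        i0 = int(np.searchsorted(times, ev["depart"]))
        i1 = (int(np.searchsorted(times, ev["arrive"]))
              if pd.notna(ev["arrive"]) else n_steps - 1)
        window = np.arange(i0, min(i1 + 1, n_steps))
        ev["depart_core"] = ev["depart"]
        ev["arrive_core"] = ev["arrive"]
        if len(window):
            d_o = np.hypot(*(pos[window] - centers[origin]).T)
            d_d = np.hypot(*(pos[window] - centers[dest]).T)
            inside_o = window[d_o < core_radius_km]
            inside_d = window[d_d < core_radius_km]
            if len(inside_o):
                ev["depart_core"] = times[int(inside_o.max())]
            if len(inside_d):
                ev["arrive_core"] = times[int(inside_d.min())]

    xy_m = pos * 1000.0
    lon, lat = proj.inverse(xy_m[:, 0], xy_m[:, 1])
    seg = np.hypot(np.diff(pos[:, 0]), np.diff(pos[:, 1]))
    steps = pd.DataFrame({
        "timestamp": times, "lon": lon, "lat": lat,
        "x": xy_m[:, 0], "y": xy_m[:, 1], "season": label, "gamma": gamma,
    })
    events_df = pd.DataFrame(events, columns=["direction", "depart", "arrive",
                                              "depart_core", "arrive_core"])
    truth = SyntheticTruth(scn.id, steps, events_df, float(seg.sum()), proj)

    fixes = _sample_fixes(scn, truth, rng)
    return fixes, truth


def _sample_fixes(scn: IndividualScenario, truth: SyntheticTruth,
                  rng: np.random.Generator) -> pd.DataFrame:
    """Hourly fix attempts along the latent path, gated by a haul-out chain."""
    n_steps = len(truth.steps)
    n_hours = (n_steps - 1) * STEP_HOURS + 1
    hours = np.arange(n_hours)
    # piecewise-linear interpolation of the latent 3-h path to hourly positions
    node_h = np.arange(n_steps) * STEP_HOURS
    hx = np.interp(hours, node_h, truth.steps["x"].to_numpy())
    hy = np.interp(hours, node_h, truth.steps["y"].to_numpy())

    # two-state haul-out chain (hourly): stationary fraction p, mean bout length b
    p = scn.haulout_stationary
    p_leave = 1.0 / max(scn.haulout_mean_bout_h, 1.0)
    p_enter = p_leave * p / max(1.0 - p, 1e-9)
    hauled = np.empty(n_hours, dtype=bool)
    hauled[0] = rng.random() < p
    u = rng.random(n_hours)
    for h in range(1, n_hours):
        hauled[h] = (u[h] >= p_leave) if hauled[h - 1] else (u[h] < p_enter)

    # state-dependent failure calibrated so the net fraction is fix_fail_prob:
    # hauled-out attempts fail at haulout_fail_factor * net (sky view can be
    # blocked by the animal's posture), at-sea attempts make up the rest
    f = scn.fix_fail_prob
    f_haul = min(1.0, scn.haulout_fail_factor * f)
    f_sea = min(1.0, (f - p * f_haul) / max(1.0 - p, 1e-9)) if f > 0 else 0.0
    fail_prob = np.where(hauled, f_haul, f_sea)
    success = rng.random(n_hours) >= fail_prob
    for g_start, g_dur in scn.long_gaps:
        success[(hours >= g_start) & (hours < g_start + g_dur)] = False

    noise = rng.standard_normal((n_hours, 2)) * scn.gps_noise_m
    lon, lat = truth.projection.inverse(hx + noise[:, 0], hy + noise[:, 1])
    times = truth.steps["timestamp"].iloc[0] + pd.to_timedelta(hours, unit="h")
    fixes = pd.DataFrame({
        "id": scn.id, "timestamp": times,
        "lon": np.where(success, lon, np.nan),
        "lat": np.where(success, lat, np.nan),
        "fix_ok": success.astype(int),
    })
    return fixes


# --------------------------------------------------------------------------
# population
# --------------------------------------------------------------------------

@dataclass
class PopulationConfig:
    """Distributions from which per-individual scenarios are drawn.

    Defaults emulate the study conditions: tagging in August on Svalbard
    beaches, winter ranges 170-430 km to the north-east, departures late
    October to early February, migrations of about 6-17 days, net fix failure
    between 25 and 66 %.
    """

    n_individuals: int = 12
    tagging_site: tuple[float, float] = (22.0, 78.2)
    start_date: str = "2015-08-10"
    years_range: tuple[int, int] = (1, 6)
    separation_km_range: tuple[float, float] = (180.0, 420.0)
    bearing_deg_range: tuple[float, float] = (20.0, 70.0)   # from north, clockwise
    depart_doy_range: tuple[int, int] = (305, 395)          # late Oct - end Jan (mod 365)
    return_doy_range: tuple[int, int] = (80, 140)
    migration_days_range: tuple[float, float] = (6.0, 17.0)
    scouting_prob: float = 0.4
    scouting_days_range: tuple[float, float] = (6.0, 13.0)
    migratory_fraction: float = 1.0   # set below 1 to draw non-migratory animals
    fix_fail_range: tuple[float, float] = (0.25, 0.66)
    step_sd_range: tuple[float, float] = (1.0, 1.6)


def draw_scenario(cfg: PopulationConfig, idx: int,
                  rng: np.random.Generator) -> IndividualScenario:
    lon0, lat0 = cfg.tagging_site
    # summer center within ~40 km of the tagging site
    summer = (lon0 + rng.uniform(-0.5, 0.5), lat0 + rng.uniform(-0.15, 0.15))
    sep = rng.uniform(*cfg.separation_km_range)
    brg = math.radians(rng.uniform(*cfg.bearing_deg_range))
    proj = AzimuthalEquidistant(*summer)
    wx = sep * 1000.0 * math.sin(brg)
    wy = sep * 1000.0 * math.cos(brg)
    wlon, wlat = proj.inverse(wx, wy)
    migratory = rng.random() < cfg.migratory_fraction
    depart = int(rng.integers(*cfg.depart_doy_range)) % 365
    scouting = []
    if migratory and rng.random() < cfg.scouting_prob:
        dur = rng.uniform(*cfg.scouting_days_range)
        start_doy = (depart - int(rng.uniform(25, 60))) % 365
        scouting.append((start_doy, float(round(dur, 1))))
    return IndividualScenario(
        id=f"SIM{idx:03d}",
        summer_center=summer,
        winter_center=(float(wlon), float(wlat)),
        start_date=cfg.start_date,
        n_years=int(rng.integers(cfg.years_range[0], cfg.years_range[1] + 1)),
        migration_depart_doy=depart if migratory else None,
        migration_return_doy=int(rng.integers(*cfg.return_doy_range)),
        migration_duration_days=float(round(rng.uniform(*cfg.migration_days_range), 1)),
        scouting=scouting,
        fix_fail_prob=float(round(rng.uniform(*cfg.fix_fail_range), 3)),
        step_sd_km=float(round(rng.uniform(*cfg.step_sd_range), 2)),
        separation_range_km=(100.0, 500.0),
    )


def simulate_population(cfg: PopulationConfig, seed: int):
    """Simulate ``cfg.n_individuals`` tracks; returns (fixes, truths, manifest).

    ``fixes`` maps id -> attempt table, ``truths`` maps id -> SyntheticTruth,
    and ``manifest`` is a JSON-serializable record of the drawn scenarios.
    """
    if cfg.n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(cfg.n_individuals + 1)
    draw_rng = np.random.default_rng(children[0])
    fixes, truths, scenarios = {}, {}, []
    for i in range(cfg.n_individuals):
        scn = draw_scenario(cfg, i, draw_rng)
        track_seed = int(children[i + 1].generate_state(1)[0] % (2 ** 31))
        fx, tr = simulate_track(scn, track_seed)
        fixes[scn.id] = fx
        truths[scn.id] = tr
        d = asdict(scn)
        d["track_seed"] = track_seed
        scenarios.append(d)
    manifest = {"seed": seed, "config": asdict(cfg), "scenarios": scenarios}
    return fixes, truths, manifest


# --------------------------------------------------------------------------
# ice field
# --------------------------------------------------------------------------

@dataclass
class SyntheticIceFieldSpec:
    """Seasonally varying, latitude-graded categorical ice concentration.

    The latent concentration (fraction in [0, 1]) at latitude phi on
    day-of-year d is ``base + lat_gradient*(phi - lat_min) +
    seasonal_amplitude*cos(2*pi*(d - seasonal_peak_doy)/365) + noise(day)``,
    clipped to [0, 1] and then quantized into the six operational chart
    classes via ``category_edges``.
    """

    lon_min: float = 15.0
    lon_max: float = 40.0
    lat_min: float = 76.0
    lat_max: float = 82.5
    start_date: str = "2015-08-10"
    end_date: str = "2016-08-10"
    base: float = 0.05
    lat_gradient: float = 0.10          # concentration per degree latitude
    seasonal_amplitude: float = 0.55
    seasonal_peak_doy: int = 75         # mid-March maximum
    noise_sd: float = 0.04              # day-to-day jitter (spatially uniform)
    missing_dates: list[str] = field(default_factory=list)
    category_edges: tuple[float, ...] = (0.15, 0.40, 0.675, 0.875, 0.975)

    def validate(self) -> None:
        if self.lon_max <= self.lon_min or self.lat_max <= self.lat_min:
            raise ValueError("degenerate ice-field region")
        if pd.Timestamp(self.end_date) < pd.Timestamp(self.start_date):
            raise ValueError("empty ice-field date range")


ICE_CATEGORY_ORDER = list(ICE_CATEGORY_CONCENTRATION)


@dataclass
class IceChart:
    """One day's chart: polygons in lon/lat tagged with a chart category."""

    date: pd.Timestamp
    polygons: list[tuple[Polygon, str]]

    def to_geojson(self, path: str | Path) -> None:
        features = [
            {"type": "Feature", "properties": {"category": cat},
             "geometry": mapping(poly)}
            for poly, cat in self.polygons
        ]
        obj = {"type": "FeatureCollection",
               "properties": {"date": self.date.strftime("%Y-%m-%d")},
               "features": features}
        Path(path).write_text(json.dumps(obj))

    @classmethod
    def from_geojson(cls, path: str | Path) -> "IceChart":
        obj = json.loads(Path(path).read_text())
        date = pd.Timestamp(obj.get("properties", {}).get("date")
                            or Path(path).stem)
        polys = [(shape(f["geometry"]), f["properties"]["category"])
                 for f in obj["features"]]
        return cls(date, polys)


def ice_concentration_fraction(spec: SyntheticIceFieldSpec, lat, doy: int,
                               noise: float = 0.0):
    """Latent (unquantized) concentration fraction of the generator field."""
    seasonal = spec.seasonal_amplitude * np.cos(
        2.0 * np.pi * (doy - spec.seasonal_peak_doy) / 365.0)
    c = spec.base + spec.lat_gradient * (np.asarray(lat, dtype=float) - spec.lat_min) \
        + seasonal + noise
    return np.clip(c, 0.0, 1.0)


def quantize_ice(conc_fraction, edges) -> np.ndarray:
    """Map latent concentration fractions to chart category names."""
    idx = np.searchsorted(np.asarray(edges), np.asarray(conc_fraction, dtype=float),
                          side="right")
    cats = np.asarray(ICE_CATEGORY_ORDER, dtype=object)
    return cats[idx]


def simulate_ice_field(spec: SyntheticIceFieldSpec, seed: int) -> list[IceChart]:
    """One chart per day in the range, minus requested missing dates.

    Because the daily noise is spatially uniform, the category on a given day
    is a monotone function of latitude alone; each chart is therefore a stack
    of latitude-band polygons whose edges sit exactly at the quantization
    boundaries of the latent field.
    """
    spec.validate()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x1CE]))
    dates = pd.date_range(spec.start_date, spec.end_date, freq="D")
    missing = {pd.Timestamp(d) for d in spec.missing_dates}
    # AR(1)-smoothed daily jitter so consecutive charts are coherent
    eps = rng.standard_normal(len(dates)) * spec.noise_sd
    noise = np.empty(len(dates))
    acc = 0.0
    for i, e in enumerate(eps):
        acc = 0.8 * acc + math.sqrt(1 - 0.8 ** 2) * e
        noise[i] = acc

    charts = []
    edges = np.asarray(spec.category_edges)
    for i, date in enumerate(dates):
        if date in missing:
            continue
        doy = date.dayofyear
        offset = (spec.base
                  + spec.seasonal_amplitude * math.cos(
                      2.0 * math.pi * (doy - spec.seasonal_peak_doy) / 365.0)
                  + noise[i])
        # latitude at which the latent field crosses each category edge
        if spec.lat_gradient > 0:
            lat_edges = spec.lat_min + (edges - offset) / spec.lat_gradient
        else:
            lat_edges = np.full(len(edges), np.inf) * np.where(edges >= offset, 1, -1)
        bounds = np.concatenate([[spec.lat_min],
                                 np.clip(lat_edges, spec.lat_min, spec.lat_max),
                                 [spec.lat_max]])
        polygons = []
        for k in range(len(bounds) - 1):
            lo, hi = bounds[k], bounds[k + 1]
            if hi - lo <= 1e-9:
                continue
            poly = Polygon([(spec.lon_min, lo), (spec.lon_max, lo),
                            (spec.lon_max, hi), (spec.lon_min, hi)])
            polygons.append((poly, ICE_CATEGORY_ORDER[k]))
        charts.append(IceChart(date, polygons))
    return charts


def write_ice_series(charts: list[IceChart], directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for chart in charts:
        chart.to_geojson(directory / f"{chart.date.strftime('%Y%m%d')}.geojson")


def read_ice_series(directory: str | Path) -> list[IceChart]:
    return [IceChart.from_geojson(p)
            for p in sorted(Path(directory).glob("*.geojson"))]


# --------------------------------------------------------------------------
# bathymetry
# --------------------------------------------------------------------------

def synthetic_bathymetry(lon_min: float, lon_max: float, lat_min: float,
                         lat_max: float, cell_deg: float = 0.05) -> Raster:
    """Deterministic shelf-slope depth raster in lon/lat.

    A synthetic coastline runs along the southern edge of the region; depth
    grows from ~20 m at the coast towards ~600 m offshore with an exponential
    shelf profile. Positive values are metres of water depth.
    """
    if lon_max <= lon_min or lat_max <= lat_min:
        raise ValueError("degenerate bathymetry region")
    grid = Grid.from_bounds(lon_min, lat_min, lon_max, lat_max, cell_deg,
                            crs="lonlat", pad_cells=0)
    xs, ys = grid.cell_centers()
    d_km = (ys[:, None] - lat_min) * 111.19 + np.zeros((1, grid.n_cols))
    depth = 20.0 + 580.0 * (1.0 - np.exp(-np.maximum(d_km, 0.0) / 80.0))
    return Raster(grid, depth)


# --------------------------------------------------------------------------
# fix-table I/O
# --------------------------------------------------------------------------

def write_fixes(fixes: pd.DataFrame, path: str | Path) -> None:
    out = fixes.copy()
    out["timestamp"] = out["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False, float_format="%.8f")


def read_fixes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in FIX_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"fix table {path} lacks required columns {missing}")
    df["timestamp"] = pd.to_datetime(df["timestamp"], format="%Y-%m-%dT%H:%M:%S")
    return df[FIX_COLUMNS]


def write_truth(truth: SyntheticTruth, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    steps = truth.steps.copy()
    steps["timestamp"] = steps["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    steps.to_csv(directory / f"{truth.id}_latent.csv", index=False)
    ev = truth.events.copy()
    for c in ("depart", "arrive", "depart_core", "arrive_core"):
        ev[c] = pd.to_datetime(ev[c]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    ev.to_csv(directory / f"{truth.id}_events.csv", index=False)
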