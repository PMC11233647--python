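"""End-to-end orchestration: simulate (or load) fixes, then run the full
analysis chain and write report tables.

Stage order mirrors the analysis design: preprocessing; a first seasonal
classification from the distance threshold alone; seasonal utilization
distributions from that classification; migration timing refined with the
10-km buffers around the resulting core areas; time-spent-in-area maps;
environmental annotation; and finally the move-persistence mixed models.
The threshold-then-UD-then-buffer ordering breaks the circularity between
core areas (which need seasons) and migration buffers (which need core
areas).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import environment as env
from . import home_range as hr
from . import movement as mv
from . import preprocess as pp
from . import segmentation as sg
from . import synthetic as syn
from . import tsa as tsa_mod

log = logging.getLogger("tusktrack.pipeline")


@dataclass
class PipelineConfig:
    """Declarative configuration with defaults matching the analysis design:
    3-h steps, 2 m/s, 2-h gap, 96-h interpolation limit, 14-day rule, 10-km
    buffers, 500-m UD cells, 3-km TSA cells, 0.05-degree ice grid and
    isopleth levels 0.5 / 0.95."""

    out_dir: str = "runs/run"
    seed: int = 1
    # input: either synthetic population or a directory of fix CSVs
    synthetic: bool = True
    population: dict = field(default_factory=dict)
    fixes_dir: str | None = None
    tagging_site: tuple[float, float] | None = None
    # preprocessing
    step_hours: float = 3.0
    vmax: float = 2.0
    vmax_screen: float = 10.0
    gap_hours: float = 2.0
    max_gap_hours: float = 96.0
    # segmentation
    min_days: float = 14.0
    buffer_km: float = 10.0
    cap_km: float | None = None
    outlier_days: float = 40.0
    # home range / TSA
    ud_cell_m: float = 500.0
    tsa_cell_m: float = 3000.0
    levels: tuple[float, float] = (0.5, 0.95)
    # environment
    ice_cell_deg: float = 0.05
    ice_field: dict = field(default_factory=dict)
    annotate_environment: bool = True
    fit_movement_models: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _year_index(ts: pd.Series, t0: pd.Timestamp) -> np.ndarray:
    return (np.floor((ts - t0).dt.total_seconds() / 86400.0 / 365.0)
            .astype(int) + 1)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns a result bundle of DataFrames and writes CSVs."""
    t_start = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {"config": asdict(config)}

    # ---- stage 0: data ----------------------------------------------------
    if config.synthetic:
        pop = syn.PopulationConfig(**config.population)
        fixes, truths, manifest = syn.simulate_population(pop, config.seed)
        (out / "manifest.json").write_text(json.dumps(manifest, default=str, indent=1))
        tagging_site = config.tagging_site or pop.tagging_site
        results["truths"] = truths
    else:
        if not config.fixes_dir or config.tagging_site is None:
            raise ValueError("non-synthetic runs need fixes_dir and tagging_site")
        fixes = {}
        for p in sorted(Path(config.fixes_dir).glob("*.csv")):
            df = syn.read_fixes(p)
            fixes[str(df["id"].iloc[0])] = df
        tagging_site = config.tagging_site
        truths = {}
    log.info("stage data: %d individuals", len(fixes))

    # ---- per-individual chain --------------------------------------------
    table1_rows, seg_tables, event_tables, dist_tables = [], [], [], []
    tsa_rows, overlap_rows, area_rows, centroid_rows = [], [], [], []
    gamma_tables = []
    tracks: dict[str, pp.RegularTrack] = {}

    for tid, fx in fixes.items():
        screened, report = pp.screen_fixes(fx, config.vmax_screen)
        stats = pp.daily_fix_statistics(screened, config.gap_hours)
        stats.update({"id": tid, **{f"removed_{k}": v for k, v in report.items()}})
        table1_rows.append(stats)
        track = pp.regularize(screened, config.step_hours, config.vmax,
                              config.max_gap_hours)
        tracks[tid] = track

        thr = sg.distance_threshold(track, tagging_site, config.cap_km)
        seg1 = sg.classify_seasons(track, thr, config.min_days)

        # pooled seasonal UDs for core areas (scouting excluded by label)
        d = track.data
        season_of = _label_positions(d["timestamp"], seg1)
        core_polys = {}
        for season in ("summer", "winter"):
            m = season_of == season
            if m.sum() >= 5:
                ud = hr.kernel_ud(d.loc[m, "x"], d.loc[m, "y"],
                                  cell=config.ud_cell_m, season=season)
                core_polys[season] = hr.isopleth(ud, 0.5).polygon()
        events = sg.migration_timing(track, seg1, core_polys,
                                     config.buffer_km, config.outlier_days)
        seg2 = sg.apply_migration_labels(seg1, events)
        seg2.insert(0, "id", tid)
        events.insert(0, "id", tid)
        seg_tables.append(seg2)
        event_tables.append(events)

        yd = sg.cumulative_distance(screened, fx["timestamp"].iloc[0])
        yd.insert(0, "id", tid)
        dist_tables.append(yd)

        # season-instance UDs: areas, centroids, year-to-year overlap
        t0 = d["timestamp"].iloc[0]
        inst = _season_instances(seg1, t0)
        uds: dict[tuple[str, int], hr.UtilizationDistribution] = {}
        for season, year, start, end in inst:
            m = (d["timestamp"] >= start) & (d["timestamp"] < end) & \
                (season_of == season)
            complete = hr.season_long_enough(start, end)
            if m.sum() < 5:
                continue
            ud = hr.kernel_ud(d.loc[m, "x"], d.loc[m, "y"],
                              cell=config.ud_cell_m, season=season, year=year)
            uds[(season, year)] = ud
            area_rows.append({"id": tid, "season": season, "year": year,
                              "area_km2": hr.core_area_size(ud, 0.5),
                              "complete": complete})
            if m.sum() >= 3:
                cx, cy, _ = hr.mcp_centroid(d.loc[m, "x"], d.loc[m, "y"], 0.5)
                clon, clat = track.projection.inverse(cx, cy)
                centroid_rows.append({"id": tid, "season": season, "year": year,
                                      "lon": float(clon), "lat": float(clat),
                                      "complete": complete})
        for (season, year), ud in uds.items():
            nxt = uds.get((season, year + 1))
            if nxt is None:
                continue
            for level in config.levels:
                ov = hr.phr_overlap(nxt, hr.isopleth(ud, level))
                overlap_rows.append({"id": tid, "season": season,
                                     "year_pair": f"{year}-{year + 1}",
                                     "level": level, "raw": ov.raw,
                                     "rescaled": ov.rescaled})

        raster = tsa_mod.time_spent_in_area(track, cell=config.tsa_cell_m)
        _, p99 = tsa_mod.tsa_percentiles(raster)
        tsa_rows.append({"id": tid, "total_hours": float(raster.values.sum()),
                         "p99_hours": p99})

        if config.fit_movement_models:
            gam = mv.estimate_move_persistence(track)
            gam["season"] = _label_positions(gam["timestamp"], seg2)
            gam["year"] = _year_index(pd.Series(pd.to_datetime(gam["timestamp"])), t0)
            gam["tid"] = gam["id"].astype(str) + ":" + gam["year"].astype(str)
            # positions for annotation
            pos = d.set_index("timestamp").loc[pd.to_datetime(gam["timestamp"])]
            gam["lon"] = pos["lon"].to_numpy()
            gam["lat"] = pos["lat"].to_numpy()
            gamma_tables.append(gam)
        log.info("individual %s done", tid)

    table1 = pd.DataFrame(table1_rows)
    segs = pd.concat(seg_tables, ignore_index=True)
    events = pd.concat(event_tables, ignore_index=True)
    distances = pd.concat(dist_tables, ignore_index=True)
    overlaps = pd.DataFrame(overlap_rows)
    areas = pd.DataFrame(area_rows)
    centroids = pd.DataFrame(centroid_rows)
    tsa_table = pd.DataFrame(tsa_rows)

    for name, df in [("table1_tag_performance", table1),
                     ("segmentation", segs), ("migration_events", events),
                     ("table2_yearly_distance", distances),
                     ("fig7_overlap", overlaps), ("fig7_areas", areas),
                     ("centroids", centroids), ("fig4_tsa", tsa_table)]:
        df.to_csv(out / f"{name}.csv", index=False)

    results.update(table1=table1, segmentation=segs, events=events,
                   distances=distances, overlaps=overlaps, areas=areas,
                   centroids=centroids, tsa=tsa_table, tracks=tracks)

    # ---- environment ------------------------------------------------------
    if config.annotate_environment and tracks:
        all_pos = pd.concat([tr.data for tr in tracks.values()])
        lon_min, lon_max = all_pos["lon"].min() - 1, all_pos["lon"].max() + 1
        lat_min, lat_max = all_pos["lat"].min() - 0.5, all_pos["lat"].max() + 0.5
        dates = (all_pos["timestamp"].min().normalize(),
                 all_pos["timestamp"].max().normalize())
        ice_kwargs = dict(lon_min=lon_min, lon_max=lon_max, lat_min=lat_min,
                          lat_max=lat_max, start_date=str(dates[0].date()),
                          end_date=str(dates[1].date()))
        ice_kwargs.update(config.ice_field)
        charts = syn.simulate_ice_field(syn.SyntheticIceFieldSpec(**ice_kwargs),
                                        config.seed + 1)
        series = env.IceChartSeries.from_charts(charts, config.ice_cell_deg)
        bathy = syn.synthetic_bathymetry(lon_min, lon_max, lat_min, lat_max)
        bathy.write_ascii(out / "bathymetry.asc")

        ann_tables = []
        for tid, track in tracks.items():
            d = track.data
            ann = pd.DataFrame({
                "id": tid, "timestamp": d["timestamp"],
                "lon": d["lon"], "lat": d["lat"],
                "daylight_h": env.daylight_hours(d["lat"].to_numpy(),
                                                 d["lon"].to_numpy(),
                                                 d["timestamp"]),
                "depth_m": env.depth_at_positions(d["lon"], d["lat"], bathy),
                "ice_pct": env.ice_at_positions(d["timestamp"], d["lon"],
                                                d["lat"], series),
            })
            ann_tables.append(ann)
        annotations = pd.concat(ann_tables, ignore_index=True)
        annotations.to_csv(out / "env_annotations.csv", index=False)
        results["annotations"] = annotations
        results["ice_series"] = series

        # pre-migration windows across individuals -> Table-3 style fit
        win_rows = []
        for tid in tracks:
            ev = events[(events["id"] == tid)
                        & (events["direction"] == "to-winter")
                        & (~events["excluded"])]
            ann = annotations[annotations["id"] == tid]
            for _, row in ev.iterrows():
                try:
                    w = env.premigration_windows(
                        ann.rename(columns={"timestamp": "timestamp"}),
                        row["departure"])
                except ValueError:
                    continue
                w["id"] = tid
                w["year"] = pd.Timestamp(row["departure"]).year
                win_rows.append(w)
        if win_rows:
            windows = pd.concat(win_rows, ignore_index=True).dropna(
                subset=["ice_pct"])
            results["premigration_windows"] = windows
            if windows["id"].nunique() >= 2:
                fit = env.fit_premigration_model(windows, transform="none")
                fit.coefficients.to_csv(out / "table3_premigration.csv",
                                        index=False)
                results["premigration_fit"] = fit

        # movement mixed models per season
        if config.fit_movement_models and gamma_tables:
            gammas = pd.concat(gamma_tables, ignore_index=True)
            gammas["ice_pct"] = env.ice_at_positions(
                gammas["timestamp"], gammas["lon"], gammas["lat"], series)
            gammas["depth_m"] = env.depth_at_positions(
                gammas["lon"], gammas["lat"], bathy)
            gammas.to_csv(out / "gamma_series.csv", index=False)
            results["gamma_series"] = gammas
            rankings = []
            for season in ("summer", "winter"):
                sub = gammas[gammas["season"] == season]
                data = mv.prepare_covariates(sub)
                if data["id"].nunique() < 2 or len(data) < 50:
                    continue
                rank = mv.rank_models(data)
                rank.insert(0, "season", season)
                rankings.append(rank)
            if rankings:
                table4 = pd.concat(rankings, ignore_index=True)
                table4.to_csv(out / "table4_model_ranking.csv", index=False)
                results["model_ranking"] = table4

    run_log = {"seed": config.seed, "n_individuals": len(fixes),
               "elapsed_s": round(time.time() - t_start, 1),
               "parameters": asdict(config)}
    (out / "run_log.json").write_text(json.dumps(run_log, default=str, indent=1))
    log.info("pipeline finished in %.1f s", run_log["elapsed_s"])
    return results


def _label_positions(timestamps, segmentation: pd.DataFrame) -> pd.Series:
    """Season label of each timestamp from an interval table."""
    ts = pd.to_datetime(pd.Series(np.asarray(timestamps)))
    labels = pd.Series("summer", index=ts.index, dtype=object)
    for _, iv in segmentation.iterrows():
        m = (ts >= iv["start"]) & (ts < iv["end"])
        labels[m] = iv["label"]
    # the final instant belongs to the last interval
    last = segmentation.iloc[-1]
    labels[ts == last["end"]] = last["label"]
    return labels


def _season_instances(segmentation: pd.DataFrame, t0: pd.Timestamp):
    """(season, year_index, start, end) for each summer/winter interval;
    the year index counts instances of that season in order."""
    counts = {"summer": 0, "winter": 0}
    out = []
    for _, iv in segmentation.iterrows():
        if iv["label"] not in counts:
            continue
        counts[iv["label"]] += 1
        out.append((iv["label"], counts[iv["label"]], iv["start"], iv["end"]))
    return out
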