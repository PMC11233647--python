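"""Seasonal segmentation: distance thresholds, the 14-day rule, scouting
trips, buffer-based migration timing, and yearly cumulative distance.

An animal is "in the winter range" when it has spent at least 14 consecutive
days beyond an individual distance threshold from its tagging site — the
threshold being the mean great-circle distance from the tagging site to all
of the animal's 3-h interpolated positions. Excursions beyond the threshold
shorter than 14 days are scouting trips and count as part of the summer
habitat. An optional cap bounds the threshold for animals whose wide
ranging inflates the mean (in the source analysis one far-ranging animal
had its 283 km threshold capped at the 163 km maximum of the others).

Migration timing is refined with core areas: a migration starts when the
animal last leaves a 10-km buffer around its origin core area before
crossing the distance threshold, and ends when it first enters the buffered
destination core area. Migration duration and path distance use the
interpolated track (robust to gaps); yearly cumulative distances use the
raw fixes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import Point
from shapely.prepared import prep

from .geo import great_circle_km
from .preprocess import RegularTrack

MIN_WINTER_DAYS = 14.0
DEFAULT_BUFFER_KM = 10.0
DEFAULT_OUTLIER_DAYS = 40.0

LABELS = ("summer", "winter", "scouting", "migration")


@dataclass
class SeasonThreshold:
    id: str
    tagging_site: tuple[float, float]   # (lon, lat)
    threshold_km: float
    capped: bool = False


def distance_threshold(track: RegularTrack, tagging_site,
                       cap_km: float | None = None) -> SeasonThreshold:
    """Mean great-circle distance from the tagging site to all 3-h positions,
    optionally capped at ``cap_km``."""
    d = track.data
    if d.empty:
        raise ValueError("empty track")
    dist = great_circle_km(tagging_site[0], tagging_site[1],
                           d["lon"].to_numpy(), d["lat"].to_numpy())
    mean_km = float(np.mean(dist))
    if cap_km is not None and mean_km > cap_km:
        return SeasonThreshold(str(d["id"].iloc[0]), tuple(tagging_site),
                               float(cap_km), capped=True)
    return SeasonThreshold(str(d["id"].iloc[0]), tuple(tagging_site), mean_km)


def classify_seasons(track: RegularTrack, threshold: SeasonThreshold,
                     min_days: float = MIN_WINTER_DAYS) -> pd.DataFrame:
    """Label the track span as summer / winter / scouting intervals.

    Maximal runs of positions beyond the threshold lasting at least
    ``min_days`` (elapsed time) are winter; shorter ones are scouting;
    everything else is summer. Winter onsets outside December-April only
    raise a warning — the calendar is a diagnostic, not a constraint.
    Returns a frame (label, start, end) of non-overlapping intervals
    covering the span.
    """
    if threshold.threshold_km <= 0:
        raise ValueError("distance threshold must be positive")
    d = track.data
    t = d["timestamp"].reset_index(drop=True)
    beyond = great_circle_km(threshold.tagging_site[0], threshold.tagging_site[1],
                             d["lon"].to_numpy(), d["lat"].to_numpy()
                             ) > threshold.threshold_km
    intervals: list[dict] = []
    i = 0
    n = len(beyond)
    while i < n:
        j = i
        while j + 1 < n and beyond[j + 1] == beyond[i]:
            j += 1
        start, end = t[i], t[j]
        if beyond[i]:
            days = (end - start).total_seconds() / 86400.0
            label = "winter" if days >= min_days else "scouting"
        else:
            label = "summer"
        intervals.append({"label": label, "start": start, "end": end})
        i = j + 1
    # merge adjacent same-label intervals and make the cover contiguous
    merged: list[dict] = []
    for iv in intervals:
        if merged and merged[-1]["label"] == iv["label"]:
            merged[-1]["end"] = iv["end"]
        else:
            merged.append(dict(iv))
    for a, b in zip(merged[:-1], merged[1:]):
        b["start"] = a["end"]
    seg = pd.DataFrame(merged, columns=["label", "start", "end"])
    for _, row in seg[seg["label"] == "winter"].iterrows():
        if row["start"].month not in (12, 1, 2, 3, 4):
            warnings.warn(
                f"winter onset at {row['start']} falls outside December-April"
            )
    return seg


@dataclass
class MigrationEvent:
    direction: str            # "to-winter" | "to-summer"
    departure: pd.Timestamp
    arrival: pd.Timestamp
    duration_days: float
    distance_km: float
    excluded: bool = False


def migration_timing(track: RegularTrack, segmentation: pd.DataFrame,
                     core_polygons: dict, buffer_km: float = DEFAULT_BUFFER_KM,
                     outlier_days: float = DEFAULT_OUTLIER_DAYS) -> pd.DataFrame:
    """Buffer-based migration events for each summer<->winter transition.

    ``core_polygons`` maps season name -> shapely geometry of the 50% UD
    region in the track's projected frame. Departure is the last position
    inside the buffered origin region before the transition; arrival is the
    first position inside the buffered destination region after it. Events
    longer than ``outlier_days`` are flagged ``excluded`` (kept in the
    table). Transitions lacking a core area are skipped with a warning.
    """
    d = track.data.reset_index(drop=True)
    t = d["timestamp"]
    pts = np.column_stack([d["x"].to_numpy(), d["y"].to_numpy()])
    buffered = {}
    for season, poly in core_polygons.items():
        if poly is not None and not poly.is_empty:
            buffered[season] = prep(poly.buffer(buffer_km * 1000.0))

    resident = segmentation[segmentation["label"].isin(["summer", "winter"])]
    resident = resident.reset_index(drop=True)
    events = []
    for k in range(len(resident) - 1):
        a, b = resident.iloc[k], resident.iloc[k + 1]
        if a["label"] == b["label"]:
            continue
        direction = "to-winter" if b["label"] == "winter" else "to-summer"
        if a["label"] not in buffered or b["label"] not in buffered:
            warnings.warn(
                f"missing core area for {a['label']} or {b['label']}; "
                f"skipping {direction} event at {b['start']}"
            )
            continue
        origin, dest = buffered[a["label"]], buffered[b["label"]]
        # departure: last position in the buffered origin up to the transition
        win_a = np.flatnonzero((t >= a["start"]) & (t <= b["start"]))
        dep_idx = None
        for i in win_a[::-1]:
            if origin.contains(Point(pts[i])):
                dep_idx = i
                break
        # arrival: first position in the buffered destination from transition on
        win_b = np.flatnonzero((t >= b["start"]) & (t <= b["end"]))
        arr_idx = None
        for i in win_b:
            if dest.contains(Point(pts[i])):
                arr_idx = i
                break
        if dep_idx is None or arr_idx is None or arr_idx <= dep_idx:
            warnings.warn(f"could not resolve {direction} event at {b['start']}")
            continue
        seg_len = np.hypot(np.diff(pts[dep_idx:arr_idx + 1, 0]),
                           np.diff(pts[dep_idx:arr_idx + 1, 1])).sum() / 1000.0
        dur = (t[arr_idx] - t[dep_idx]).total_seconds() / 86400.0
        events.append(MigrationEvent(direction, t[dep_idx], t[arr_idx],
                                     float(dur), float(seg_len),
                                     excluded=dur > outlier_days))
    return pd.DataFrame([e.__dict__ for e in events],
                        columns=["direction", "departure", "arrival",
                                 "duration_days", "distance_km", "excluded"])


def apply_migration_labels(segmentation: pd.DataFrame,
                           events: pd.DataFrame) -> pd.DataFrame:
    """Carve migration intervals (departure..arrival) out of the seasonal
    cover so the final labelling uses all four labels."""
    pieces = []
    cuts = [(row["departure"], row["arrival"]) for _, row in events.iterrows()
            if not row["excluded"]]
    for _, iv in segmentation.iterrows():
        start, end, label = iv["start"], iv["end"], iv["label"]
        spans = [(start, end, label)]
        for dep, arr in cuts:
            new = []
            for s, e, lab in spans:
                if arr <= s or dep >= e:
                    new.append((s, e, lab))
                    continue
                if s < dep:
                    new.append((s, dep, lab))
                new.append((max(s, dep), min(e, arr), "migration"))
                if e > arr:
                    new.append((arr, e, lab))
            spans = new
        pieces.extend(spans)
    out = pd.DataFrame(pieces, columns=["start", "end", "label"])
    out = out[out["start"] < out["end"]].reset_index(drop=True)
    merged = []
    for _, iv in out.iterrows():
        if merged and merged[-1]["label"] == iv["label"] and \
                merged[-1]["end"] == iv["start"]:
            merged[-1]["end"] = iv["end"]
        else:
            merged.append(dict(iv))
    return pd.DataFrame(merged, columns=["label", "start", "end"])


def cumulative_distance(raw_fixes: pd.DataFrame, instrumentation,
                        window_days: float = 365.0) -> pd.DataFrame:
    """Yearly cumulative distance from the raw (screened) successful fixes.

    Years are consecutive ``window_days`` windows from the instrumentation
    time; each inter-fix leg is assigned to the window containing its start.
    Partial terminal windows report their actual day count.
    """
    ok = raw_fixes[raw_fixes["fix_ok"] == 1].sort_values("timestamp")
    t0 = pd.Timestamp(instrumentation)
    if len(ok) < 2:
        return pd.DataFrame(columns=["year", "distance_km", "days"])
    lon = ok["lon"].to_numpy()
    lat = ok["lat"].to_numpy()
    legs = great_circle_km(lon[:-1], lat[:-1], lon[1:], lat[1:])
    day = (ok["timestamp"] - t0).dt.total_seconds().to_numpy() / 86400.0
    year = np.floor(day[:-1] / window_days).astype(int)
    out = []
    for y in np.unique(year):
        m = year == y
        span_end = min(day[-1], (y + 1) * window_days)
        out.append({"year": int(y + 1),
                    "distance_km": float(legs[m].sum()),
                    "days": float(round(span_end - y * window_days, 1))})
    return pd.DataFrame(out)
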