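"""Animal x camera encounter tables.

Builds the analysis table joining telemetry tracks, home-range surfaces,
camera deployments and photo detections: which cameras were *available*
to which animals (spatial overlap with the 90% home-range isopleth and
temporal overlap between deployment and tracking windows, outside the
reproductive season), how many relocations fell within 250/500 m of each
camera, and whether/how often the animal was photo-detected there.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .homerange import (
    IsoplethSet,
    TelemetryTrack,
    UtilizationDistribution,
    isopleth_percentile_at,
    ud_at,
)

__all__ = [
    "CameraDeployment",
    "assign_season",
    "group_detections",
    "available_pairs",
    "count_relocations_within",
    "build_encounter_table",
    "validate_encounter_table",
]

log = logging.getLogger(__name__)

SEASONS = ("FallWinter", "Summer")
EXCLUDED = "Excluded"

#: Minimum gap between photo groups that separates detection events.
DEFAULT_MIN_GAP = pd.Timedelta(minutes=15)


@dataclass(frozen=True)
class CameraDeployment:
    """One camera station: location and deployment window (dates, inclusive)."""

    camera_id: str
    x: float
    y: float
    start: dt.date
    end: dt.date

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.camera_id}: start after end")


def assign_season(date) -> str:
    """Season of a calendar date.

    1 Oct - 15 Mar -> FallWinter; 1 Jun - 30 Sep -> Summer; the
    reproductive period 16 Mar - 31 May -> Excluded (males range widely
    for mates and females den, so space use is unrepresentative).
    """
    d = pd.Timestamp(date)
    m, day = d.month, d.day
    if m >= 10 or m <= 2 or (m == 3 and day <= 15):
        return "FallWinter"
    if 6 <= m <= 9:
        return "Summer"
    return EXCLUDED


def group_detections(
    timestamps: Iterable, min_gap: pd.Timedelta = DEFAULT_MIN_GAP
) -> list[list[pd.Timestamp]]:
    """Group image timestamps of one animal x camera into detection events.

    Images are sorted; a new event starts whenever the gap from the
    previous image is at least `min_gap` (default 15 minutes). The number
    of events is the photo count used by the count-response models.
    """
    ts = sorted(pd.Timestamp(t) for t in timestamps)
    events: list[list[pd.Timestamp]] = []
    for t in ts:
        if events and (t - events[-1][-1]) < min_gap:
            events[-1].append(t)
        else:
            events.append([t])
    return events


def _season_days(
    start: dt.date, end: dt.date, season: str | None
) -> pd.DatetimeIndex:
    """Days in [start, end] whose season matches (all non-excluded if None)."""
    if start > end:
        return pd.DatetimeIndex([])
    days = pd.date_range(start, end, freq="D")
    m, day = days.month, days.day
    fallwinter = (m >= 10) | (m <= 2) | ((m == 3) & (day <= 15))
    summer = (m >= 6) & (m <= 9)
    if season == "FallWinter":
        return days[fallwinter]
    if season == "Summer":
        return days[summer]
    if season is None:
        return days[fallwinter | summer]
    raise ValueError(f"unknown season {season!r}")


def _overlap(
    a_start: dt.date, a_end: dt.date, b_start: dt.date, b_end: dt.date
) -> tuple[dt.date, dt.date] | None:
    s, e = max(a_start, b_start), min(a_end, b_end)
    return (s, e) if s <= e else None


def available_pairs(
    tracks: Sequence[TelemetryTrack],
    surfaces: Mapping[str, tuple[UtilizationDistribution, IsoplethSet]] | None,
    deployments: Sequence[CameraDeployment],
    season_filter: str | None = None,
    truncate_at: int = 90,
) -> list[dict]:
    """Animal x camera pairs with the potential to produce a photo.

    A pair is available when (a) if `surfaces` is given, the camera sits
    inside the animal's `truncate_at`% isopleth (grid membership:
    density >= threshold), and (b) the deployment window, the tracking
    window and the non-excluded season days intersect. ``exposure_days``
    is the day count of that intersection (restricted to
    `season_filter` when given).

    Cameras with a zero-length window are dropped with a warning.
    """
    out: list[dict] = []
    for cam in deployments:
        if cam.start == cam.end:
            log.warning("camera %s has zero-length deployment; dropped", cam.camera_id)
            continue
        for track in tracks:
            if surfaces is not None:
                if track.animal_id not in surfaces:
                    continue
                ud, isos = surfaces[track.animal_id]
                dens = float(ud_at(ud, np.array([cam.x, cam.y])))
                if dens < isos.threshold(truncate_at):
                    continue
            ov = _overlap(cam.start, cam.end, track.tracking_start, track.tracking_end)
            if ov is None:
                continue
            days = _season_days(ov[0], ov[1], season_filter)
            if len(days) == 0:
                continue
            out.append(
                dict(
                    animal_id=track.animal_id,
                    camera_id=cam.camera_id,
                    window_start=ov[0],
                    window_end=ov[1],
                    exposure_days=float(len(days)),
                )
            )
    return out


def count_relocations_within(
    track: TelemetryTrack,
    camera: CameraDeployment,
    radius: float,
    window: tuple[dt.date, dt.date] | None = None,
    min_camera_spacing: float | None = None,
) -> int:
    """Relocations within `radius` metres of the camera (NLocs).

    Counting is unique across cameras only when cameras are at least
    ``2 * radius`` apart; a warning is emitted when a supplied
    `min_camera_spacing` voids that guarantee.
    """
    if min_camera_spacing is not None and radius > min_camera_spacing / 2.0:
        log.warning(
            "radius %.0f m exceeds half the minimum camera spacing %.0f m; "
            "relocations may be counted at more than one camera",
            radius,
            min_camera_spacing,
        )
    rel = track.relocations
    if window is not None:
        d = pd.to_datetime(rel["date"])
        mask = (d >= pd.Timestamp(window[0])) & (d <= pd.Timestamp(window[1]))
        rel = rel.loc[mask]
    if len(rel) == 0:
        return 0
    dx = rel["x"].to_numpy(dtype=float) - camera.x
    dy = rel["y"].to_numpy(dtype=float) - camera.y
    return int(np.count_nonzero(dx * dx + dy * dy <= radius * radius))


def _pair_events(
    detections: pd.DataFrame, min_gap: pd.Timedelta
) -> dict[tuple[str, str], list[pd.Timestamp]]:
    """Event start times per (animal, camera) after 15-min grouping."""
    out: dict[tuple[str, str], list[pd.Timestamp]] = {}
    if detections is None or len(detections) == 0:
        return out
    for (aid, cid), grp in detections.groupby(["animal_id", "camera_id"]):
        events = group_detections(grp["timestamp"], min_gap=min_gap)
        out[(str(aid), str(cid))] = [ev[0] for ev in events]
    return out


def build_encounter_table(
    tracks: Sequence[TelemetryTrack],
    surfaces: Mapping[str, tuple[UtilizationDistribution, IsoplethSet]] | None,
    deployments: Sequence[CameraDeployment],
    detections: pd.DataFrame | None,
    analysis: str = "homerange",
    radii: Sequence[float] = (250.0, 500.0),
    min_gap: pd.Timedelta = DEFAULT_MIN_GAP,
    truncate_at: int = 90,
) -> pd.DataFrame:
    """Build the per-record design table for one analysis.

    analysis="proximity": availability is temporal-overlap only and the
    proximity counts (NLocs within 250/500 m, same-season relocations)
    are filled. analysis="homerange": availability additionally requires
    the camera inside the 90% isopleth of the animal's surface for that
    record's season, and the UD/isopleth/core covariates are read off the
    same surface. `surfaces` may be keyed by ``animal_id`` or by
    ``(animal_id, season)`` when seasonal surfaces are used.

    Deployments straddling a season boundary are split into per-season
    records with exposure proportional to the days in each season.
    Detection events that fall on no available pair-window are logged
    and dropped (count reported at INFO level).
    """
    if analysis not in ("proximity", "homerange"):
        raise ValueError("analysis must be 'proximity' or 'homerange'")
    if analysis == "homerange" and surfaces is None:
        raise ValueError("homerange analysis requires UD surfaces")

    track_by_id = {t.animal_id: t for t in tracks}
    pairs = available_pairs(tracks, None, deployments, season_filter=None,
                            truncate_at=truncate_at)
    events = _pair_events(detections, min_gap)
    cam_by_id = {c.camera_id: c for c in deployments}

    rows: list[dict] = []
    used_events = 0
    for pair in pairs:
        track = track_by_id[pair["animal_id"]]
        cam = cam_by_id[pair["camera_id"]]
        for season in SEASONS:
            days = _season_days(pair["window_start"], pair["window_end"], season)
            if len(days) == 0:
                continue
            w0, w1 = days.min().date(), days.max().date()
            ev = [
                t
                for t in events.get((track.animal_id, cam.camera_id), [])
                if assign_season(t) == season
                and pd.Timestamp(w0) <= t.normalize() <= pd.Timestamp(w1)
            ]
            used_events += len(ev)
            row = dict(
                animal_id=track.animal_id,
                camera_id=cam.camera_id,
                sex=track.sex,
                season=season,
                exposure_days=float(len(days)),
                photo_count=len(ev),
                detected=int(len(ev) > 0),
            )
            if analysis == "proximity":
                for r in radii:
                    row[f"n_locs_{int(r)}"] = count_relocations_within(
                        track, cam, r, window=(w0, w1)
                    )
            else:
                key = (track.animal_id, season)
                surf = surfaces.get(key, surfaces.get(track.animal_id))
                if surf is None:  # no estimable surface for this season
                    continue
                ud, isos = surf
                dens = float(ud_at(ud, np.array([cam.x, cam.y])))
                pct = isopleth_percentile_at(
                    ud, isos, (cam.x, cam.y), truncate_at=truncate_at
                )
                if pct is None:  # outside the 90% isopleth: not available
                    continue
                row.update(ud=dens, isopleth_pct=int(pct), core=bool(pct <= 50))
                for r in radii:
                    row[f"n_locs_{int(r)}"] = count_relocations_within(
                        track, cam, r, window=(w0, w1)
                    )
            rows.append(row)

    total_events = sum(len(v) for v in events.values())
    if total_events and used_events < total_events:
        log.info(
            "%d of %d detection events fell outside available pair windows "
            "and were dropped",
            total_events - used_events,
            total_events,
        )
    df = pd.DataFrame(rows)
    if len(df):
        validate_encounter_table(df, analysis)
    return df


def validate_encounter_table(df: pd.DataFrame, analysis: str = "homerange") -> None:
    """Raise if any record violates its invariants."""
    if (df["exposure_days"] <= 0).any():
        raise AssertionError("non-positive exposure")
    if ((df["detected"] == 1) != (df["photo_count"] >= 1)).any():
        raise AssertionError("detected flag inconsistent with photo count")
    if analysis == "proximity":
        cols = [c for c in df.columns if c.startswith("n_locs_")]
        radii = sorted(int(c.rsplit("_", 1)[1]) for c in cols)
        for a, b in zip(radii, radii[1:]):
            if (df[f"n_locs_{a}"] > df[f"n_locs_{b}"]).any():
                raise AssertionError("NLocs not monotone in radius")
    else:
        if (df["ud"] < 0).any():
            raise AssertionError("negative utilization density")
        if ((df["isopleth_pct"] < 1) | (df["isopleth_pct"] > 90)).any():
            raise AssertionError("isopleth percentile outside [1, 90]")
        if ((df["isopleth_pct"] <= 50) != df["core"]).any():
            raise AssertionError("core flag inconsistent with isopleth percentile")
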