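"""CSV / grid / GeoJSON input-output.

Schemas (all dates ISO-8601, coordinates projected metres):
telemetry.csv: animal_id, sex, date, x, y
cameras.csv:   camera_id, x, y, start, end
detections.csv: camera_id, animal_id, timestamp
"""

from __future__ import annotations

import datetime as dt
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .encounters import CameraDeployment
from .homerange import IsoplethSet, TelemetryTrack, UtilizationDistribution

__all__ = [
    "read_telemetry",
    "read_cameras",
    "read_detections",
    "write_ascii_grid",
    "read_ascii_grid",
    "isopleths_to_geojson",
    "write_selection_table",
]


def read_telemetry(path) -> list[TelemetryTrack]:
    df = pd.read_csv(path, parse_dates=["date"])
    tracks = []
    for (aid, sex), grp in df.groupby(["animal_id", "sex"], sort=True):
        grp = grp.sort_values("date").reset_index(drop=True)
        tracks.append(
            TelemetryTrack(
                animal_id=str(aid),
                sex=str(sex),
                tracking_start=grp["date"].min().date(),
                tracking_end=grp["date"].max().date(),
                relocations=grp[["date", "x", "y"]],
            )
        )
    return tracks


def read_cameras(path) -> list[CameraDeployment]:
    df = pd.read_csv(path, parse_dates=["start", "end"])
    return [
        CameraDeployment(
            camera_id=str(r.camera_id),
            x=float(r.x),
            y=float(r.y),
            start=r.start.date(),
            end=r.end.date(),
        )
        for r in df.itertuples(index=False)
    ]


def read_detections(path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["timestamp"])
    return df[["camera_id", "animal_id", "timestamp"]]


def write_ascii_grid(ud: UtilizationDistribution, path) -> Path:
    """ESRI ASCII grid (rows north to south)."""
    path = Path(path)
    ny, nx = ud.density.shape
    header = (
        f"ncols {nx}\nnrows {ny}\n"
        f"xllcorner {ud.x0:.3f}\nyllcorner {ud.y0:.3f}\n"
        f"cellsize {ud.cell:.6f}\nNODATA_value -9999\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, ud.density[::-1], fmt="%.6e")
    return path


def read_ascii_grid(path) -> tuple[np.ndarray, dict]:
    meta = {}
    with open(path) as fh:
        for _ in range(6):
            k, v = fh.readline().split()
            meta[k.lower()] = float(v)
        dens = np.loadtxt(fh)[::-1]
    return dens, meta


def isopleths_to_geojson(
    ud: UtilizationDistribution, isos: IsoplethSet, path, percentiles=(50, 90, 95)
) -> Path:
    """Isopleth regions as GeoJSON multipolygons (unions of grid cells)."""
    from shapely.geometry import box, mapping
    from shapely.ops import unary_union

    feats = []
    half = ud.cell / 2.0
    xs, ys = ud.x_centers, ud.y_centers
    for p in percentiles:
        mask = ud.density >= isos.threshold(p)
        iy, ix = np.nonzero(mask)
        cells = [
            box(xs[j] - half, ys[i] - half, xs[j] + half, ys[i] + half)
            for i, j in zip(iy, ix)
        ]
        geom = unary_union(cells)
        feats.append(
            dict(
                type="Feature",
                properties=dict(percentile=int(p), area_ha=isos.area(p)),
                geometry=mapping(geom),
            )
        )
    payload = dict(type="FeatureCollection", features=feats)
    path = Path(path)
    path.write_text(json.dumps(payload))
    return path


def write_selection_table(sel: pd.DataFrame, path, fmt: str = "csv") -> Path:
    path = Path(path)
    if fmt == "csv":
        sel.to_csv(path, index=False, float_format="%.4f")
    else:
        cols = ["Model", "K", "Delta", "Weight", "CumWeight", "R2c"]
        txt = sel[cols].to_string(index=False, float_format=lambda v: f"{v:.2f}")
        crit = sel.attrs.get("criterion", "IC")
        path.write_text(f"criterion: {crit}\n{txt}\n")
    return path
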