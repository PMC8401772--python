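"""Readers and writers for trajectory and localization tables.

Canonical interchange is CSV, matching the export dialects of the common
tracking/localization tools:

* trajectory tables — canonical header ``track_id,frame,x_um,y_um,intensity``;
  the TrackMate export dialect (``TRACK_ID,FRAME,POSITION_X,POSITION_Y`` with
  declared spatial units) is also accepted;
* localization tables — the ThunderSTORM export dialect
  (``frame,x [nm],y [nm],intensity [photon]``) and a plain
  ``frame,x_nm,y_nm`` form.

All readers convert to the package's internal conventions (μm for
trajectories, nm for localization maps) and record the source units.
"""

from __future__ import annotations

from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .types import LocalizationMap, Trajectory

__all__ = [
    "read_track_csv",
    "write_track_csv",
    "read_thunderstorm_csv",
    "write_thunderstorm_csv",
]

_TRACK_SYNONYMS = {
    "track_id": ["track_id", "TRACK_ID", "particle", "trajectory"],
    "frame": ["frame", "FRAME", "t"],
    "x": ["x_um", "POSITION_X", "x"],
    "y": ["y_um", "POSITION_Y", "y"],
    "intensity": ["intensity", "TOTAL_INTENSITY", "MEAN_INTENSITY", "mass"],
}

_LOC_SYNONYMS = {
    "frame": ["frame", "FRAME"],
    "x": ["x [nm]", "x_nm", "x"],
    "y": ["y [nm]", "y_nm", "y"],
    "intensity": ["intensity [photon]", "intensity", "I"],
}


def _resolve(df: pd.DataFrame, synonyms, required) -> dict:
    cols = {}
    for key, names in synonyms.items():
        for name in names:
            if name in df.columns:
                cols[key] = name
                break
    missing = [k for k in required if k not in cols]
    if missing:
        raise ValueError(
            f"missing required column(s) {missing}; accepted headers: "
            + "; ".join(f"{k}: {synonyms[k]}" for k in missing)
        )
    return cols


def read_track_csv(path, spatial_units: str = "um", pixel_size: float = 0.225) -> List[Trajectory]:
    """Read a trajectory table (canonical or TrackMate dialect).

    ``spatial_units`` declares the file's position units: ``"um"`` (default),
    ``"nm"``, or ``"px"`` (converted with ``pixel_size`` μm/px).
    TrackMate exports carry three header rows after the column names; any
    non-numeric rows below the header are dropped.
    """
    path = Path(path)
    df = pd.read_csv(path)
    cols = _resolve(df, _TRACK_SYNONYMS, required=("track_id", "frame", "x", "y"))
    sub = df[[cols[k] for k in ("track_id", "frame", "x", "y")]].apply(
        pd.to_numeric, errors="coerce"
    )
    sub.columns = ["track_id", "frame", "x", "y"]
    if "intensity" in cols:
        sub["intensity"] = pd.to_numeric(df[cols["intensity"]], errors="coerce")
    bad = sub[["track_id", "frame", "x", "y"]].isna().any(axis=1)
    sub = sub[~bad]

    scale = {"um": 1.0, "nm": 1e-3, "px": pixel_size}.get(spatial_units)
    if scale is None:
        raise ValueError(f"unknown spatial_units: {spatial_units!r}")

    trajs = []
    for tid, g in sub.groupby("track_id", sort=True):
        g = g.sort_values("frame")
        trajs.append(
            Trajectory(
                track_id=int(tid),
                frames=g["frame"].to_numpy(dtype=np.int64),
                xy=g[["x", "y"]].to_numpy(dtype=np.float64) * scale,
                intensities=g["intensity"].to_numpy(dtype=np.float64)
                if "intensity" in g else None,
            )
        )
    return trajs


def write_track_csv(path, trajs: Sequence[Trajectory]) -> None:
    """Write trajectories in the canonical dialect (μm); lossless round-trip."""
    rows = []
    for t in trajs:
        inten = t.intensities if t.intensities is not None else np.full(t.n_points, np.nan)
        for i in range(t.n_points):
            rows.append((t.track_id, int(t.frames[i]), t.xy[i, 0], t.xy[i, 1], inten[i]))
    pd.DataFrame(rows, columns=["track_id", "frame", "x_um", "y_um", "intensity"]).to_csv(
        path, index=False
    )


def read_thunderstorm_csv(path, fov_bounds: Optional[tuple] = None,
                          source: str = "synthetic") -> LocalizationMap:
    """Read a localization table in the ThunderSTORM export dialect (nm).

    When ``fov_bounds`` is omitted it is taken as the data's bounding box.
    """
    df = pd.read_csv(path)
    cols = _resolve(df, _LOC_SYNONYMS, required=("x", "y"))
    x = pd.to_numeric(df[cols["x"]], errors="coerce")
    y = pd.to_numeric(df[cols["y"]], errors="coerce")
    ok = ~(x.isna() | y.isna())
    pts = np.column_stack([x[ok].to_numpy(), y[ok].to_numpy()])
    frame = None
    if "frame" in cols:
        frame = pd.to_numeric(df[cols["frame"]], errors="coerce")[ok].to_numpy(dtype=np.int64)
    if fov_bounds is None:
        fov_bounds = (
            float(pts[:, 0].min()), float(pts[:, 1].min()),
            float(pts[:, 0].max()), float(pts[:, 1].max()),
        )
    return LocalizationMap(points=pts, fov_bounds=fov_bounds, frame=frame, source=source)


def write_thunderstorm_csv(path, loc_map: LocalizationMap) -> None:
    """Write a localization map in the ThunderSTORM dialect (nm)."""
    df = pd.DataFrame(
        {
            "frame": loc_map.frame
            if loc_map.frame is not None
            else np.zeros(loc_map.n_points, dtype=np.int64),
            "x [nm]": loc_map.points[:, 0],
            "y [nm]": loc_map.points[:, 1],
            "intensity [photon]": np.ones(loc_map.n_points),
        }
    )
    df.to_csv(path, index=False)
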