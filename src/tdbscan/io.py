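"""Reading and writing tracking tables, labels, and reports.

Input tracking data is CSV with one row per fix: an ISO 8601 timestamp
(assumed UTC when unzoned), latitude and longitude in decimal degrees
(WGS84).  Rows with unparseable timestamps or out-of-range coordinates are
dropped and counted in the log; the remainder is sorted by (timestamp,
file order) and assigned ids 0..n-1.  Extra columns are preserved in
labelled output but ignored by the algorithm.
"""

from __future__ import annotations

import csv
import json
import logging
import re
from datetime import datetime, timezone
from typing import Sequence

import numpy as np
import pandas as pd

from .cluster import ClusterLabeling, TrackPoint
from .errors import EmptyInputError, SchemaError, ValidationError
from .geo import GeoPoint

log = logging.getLogger("tdbscan")

DEFAULT_COLUMNS = {"timestamp": "timestamp", "latitude": "latitude", "longitude": "longitude"}

__all__ = [
    "read_track_csv",
    "read_track_frame",
    "write_track_csv",
    "write_labeled_csv",
    "write_metrics_json",
    "parse_duration",
]

_DURATION_RE = re.compile(r"^\s*(\d+(?:\.\d+)?)\s*([smhd])\s*$")
_UNIT_S = {"s": 1.0, "m": 60.0, "h": 3600.0, "d": 86400.0}


def parse_duration(text: str) -> float:
    """Parse a humane duration like ``72h`` or ``3d`` into seconds."""
    m = _DURATION_RE.match(str(text))
    if not m:
        raise ValidationError(
            f"cannot parse duration {text!r}; expected <number><s|m|h|d>"
        )
    return float(m.group(1)) * _UNIT_S[m.group(2)]


def read_track_frame(
    path, column_map: dict[str, str] | None = None
) -> tuple[list[TrackPoint], pd.DataFrame]:
    """Read a tracking CSV; returns (points, valid-row DataFrame).

    The DataFrame keeps all original columns of the valid rows, in the same
    (timestamp, file order) sort as the point ids, so labelled output can
    re-emit the input columns verbatim.
    """
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in (cols["timestamp"], cols["latitude"], cols["longitude"]) if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    ts = pd.to_datetime(df[cols["timestamp"]], utc=True, errors="coerce", format="mixed")
    lat = pd.to_numeric(df[cols["latitude"]], errors="coerce")
    lon = pd.to_numeric(df[cols["longitude"]], errors="coerce")
    ok = (
        ts.notna()
        & lat.notna()
        & lon.notna()
        & lat.between(-90.0, 90.0)
        & lon.between(-180.0, 180.0)
    )
    n_dropped = int((~ok).sum())
    if n_dropped:
        log.warning("%s: dropped %d invalid row(s) of %d", path, n_dropped, len(df))
    if not ok.any():
        raise EmptyInputError(f"{path}: no valid rows after filtering")
    valid = df[ok].copy()
    valid["_t"] = ts[ok].astype("int64") / 1e9
    valid["_ord"] = np.arange(len(valid))
    valid = valid.sort_values(["_t", "_ord"], kind="stable").reset_index(drop=True)
    points = [
        TrackPoint(id=i, pos=GeoPoint(float(la), float(lo)), t=float(t))
        for i, (la, lo, t) in enumerate(
            zip(valid[cols["latitude"]], valid[cols["longitude"]], valid["_t"])
        )
    ]
    frame = valid.drop(columns=["_t", "_ord"])
    return points, frame


def read_track_csv(path, column_map: dict[str, str] | None = None) -> list[TrackPoint]:
    """Read a tracking CSV into a list of :class:`TrackPoint`."""
    points, _ = read_track_frame(path, column_map)
    return points


def _iso(t: float) -> str:
    return datetime.fromtimestamp(t, tz=timezone.utc).isoformat()


def write_track_csv(path, points: Sequence[TrackPoint]) -> None:
    """Write fixes as a tracking CSV (timestamp, latitude, longitude).

    Coordinates are written with full round-trip precision and timestamps
    at whole-second ISO 8601, so reader/writer composition is the identity
    for whole-second data.
    """
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["timestamp", "latitude", "longitude"])
        for p in points:
            w.writerow([_iso(p.t), repr(float(p.pos.lat)), repr(float(p.pos.lon))])


def write_labeled_csv(
    path, frame: pd.DataFrame, labeling: ClusterLabeling
) -> None:
    """Input columns plus ``cluster`` and ``is_core`` columns."""
    if len(frame) != len(labeling.labels):
        raise ValidationError("labeling does not cover the input rows")
    out = frame.copy()
    out["cluster"] = np.asarray(labeling.labels)
    out["is_core"] = np.asarray(labeling.is_core)
    out.to_csv(path, index=False)


def write_metrics_json(path, metrics: dict) -> None:
    with open(path, "w") as fh:
        json.dump(metrics, fh, indent=2, sort_keys=True)
        fh.write("\n")
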