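"""Stopover-site summaries: turn clusters into ecological records.

A stopover site is one cluster reduced to its centroid (unweighted mean of
member coordinates — adequate below ~25 km extents), arrival (earliest fix),
departure (latest fix), and duration in days.  Durations cover the whole
stop, not only core fixes.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from datetime import datetime, timezone
from typing import Sequence

import numpy as np

from .cluster import NOISE, ClusterLabeling, TrackPoint
from .errors import ValidationError
from .geo import GeoPoint

__all__ = ["StopoverSite", "summarize", "write_stopover_csv", "write_stopover_geojson"]


@dataclass(frozen=True)
class StopoverSite:
    """Summary of one identified stopover cluster."""

    cluster_id: int
    centroid: GeoPoint
    arrival: float  # epoch seconds UTC, earliest member fix
    departure: float  # epoch seconds UTC, latest member fix
    duration_days: float  # (departure - arrival) / 86400, 1 decimal
    n_fixes: int


def summarize(
    points: Sequence[TrackPoint], labeling: ClusterLabeling
) -> list[StopoverSite]:
    """One record per cluster, noise excluded, sorted ascending by arrival."""
    labels = np.asarray(labeling.labels)
    if len(labels) != len(points):
        raise ValidationError("labeling does not cover the point list")
    sites = []
    for cid in range(labeling.n_clusters):
        idx = np.flatnonzero(labels == cid)
        if len(idx) == 0:
            continue
        ts = np.array([points[i].t for i in idx])
        lats = np.array([points[i].pos.lat for i in idx])
        lons = np.array([points[i].pos.lon for i in idx])
        arrival, departure = float(ts.min()), float(ts.max())
        sites.append(
            StopoverSite(
                cluster_id=cid,
                centroid=GeoPoint(float(lats.mean()), float(lons.mean())),
                arrival=arrival,
                departure=departure,
                duration_days=round((departure - arrival) / 86400.0, 1),
                n_fixes=len(idx),
            )
        )
    sites.sort(key=lambda s: (s.arrival, s.cluster_id))
    return sites


def _iso(t: float) -> str:
    return datetime.fromtimestamp(t, tz=timezone.utc).isoformat()


def write_stopover_csv(sites: Sequence[StopoverSite], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(
            [
                "cluster_id",
                "centroid_lat",
                "centroid_lon",
                "arrival_iso",
                "departure_iso",
                "duration_days",
                "n_fixes",
            ]
        )
        for s in sites:
            w.writerow(
                [
                    s.cluster_id,
                    repr(float(s.centroid.lat)),
                    repr(float(s.centroid.lon)),
                    _iso(s.arrival),
                    _iso(s.departure),
                    s.duration_days,
                    s.n_fixes,
                ]
            )


def write_stopover_geojson(sites: Sequence[StopoverSite], path) -> None:
    """RFC 7946 FeatureCollection of Point features ([lon, lat] order)."""
    features = [
        {
            "type": "Feature",
            "geometry": {
                "type": "Point",
                "coordinates": [s.centroid.lon, s.centroid.lat],
            },
            "properties": {
                "cluster_id": s.cluster_id,
                "arrival_iso": _iso(s.arrival),
                "departure_iso": _iso(s.departure),
                "duration_days": s.duration_days,
                "n_fixes": s.n_fixes,
            },
        }
        for s in sites
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh, indent=2)
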