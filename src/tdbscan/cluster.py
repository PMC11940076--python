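"""Temporal density clustering of tracking fixes (T-DBSCAN) and a classic
DBSCAN baseline.

T-DBSCAN replaces DBSCAN's minimum-neighbour-count (MinPts) density test
with a dwell-time test: a fix is a *core object* when the time span of its
*temporal neighbourhood* — the maximal time-contiguous run of its spatial
eps-neighbourhood, with consecutive gaps bounded by ``max_interval_s``,
containing the fix itself — is at least ``min_stay_s``.  Clusters are the
maximal temporally-density-connected sets.  Two optimisations, both
switchable, accelerate the scan:

* a quadtree spatial index answering eps-radius neighbourhood queries
  (provably result-identical to a linear scan, since the exact haversine
  filter follows the bounding-box prune); and
* convex-hull-guided expansion, which enqueues only the hull vertices of
  each newly claimed temporal neighbourhood for further queries.  Interior
  points are labelled but never queried, which can omit points reachable
  only through an interior fix — a bounded (~1%) approximation.

Scan order is deterministic ascending-id; cluster ids are assigned in
discovery order.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Sequence

import math

import numpy as np

from .errors import ContractViolationError, ValidationError
from .geo import (
    GeoPoint,
    QuadTree,
    check_antimeridian,
    convex_hull_indices,
    haversine_km_arrays,
    project_local_arrays,
)

NOISE = -1

__all__ = [
    "NOISE",
    "TrackPoint",
    "TDBSCANParams",
    "ClusterLabeling",
    "temporal_neighborhood",
    "is_core",
    "tdbscan",
    "dbscan_baseline",
]


@dataclass(frozen=True)
class TrackPoint:
    """One satellite fix: integer id, position, and UTC timestamp (epoch s)."""

    id: int
    pos: GeoPoint
    t: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.t):
            raise ValidationError(f"non-finite timestamp for point {self.id}")


@dataclass(frozen=True)
class TDBSCANParams:
    """The three knobs of the algorithm plus optimisation switches.

    eps_km
        Spatial neighbourhood radius in km (reference value: 25 km).
    min_stay_s
        Minimum dwell time (span of the temporal neighbourhood) for a fix
        to be a core object, in seconds (reference value: 72 h).
    max_interval_s
        Maximum admissible gap between consecutive fixes of a temporal
        neighbourhood, in seconds (reference value: 3 d).
    """

    eps_km: float = 25.0
    min_stay_s: float = 72 * 3600.0
    max_interval_s: float = 3 * 86400.0
    use_quadtree: bool = True
    use_hull: bool = True

    def __post_init__(self) -> None:
        if not (math.isfinite(self.eps_km) and self.eps_km > 0):
            raise ValidationError("eps_km must be > 0")
        if not (math.isfinite(self.min_stay_s) and self.min_stay_s >= 0):
            raise ValidationError("min_stay_s must be >= 0")
        if not (math.isfinite(self.max_interval_s) and self.max_interval_s > 0):
            raise ValidationError("max_interval_s must be > 0")


@dataclass
class ClusterLabeling:
    """Per-point cluster assignment.

    ``labels[i]`` is -1 (noise) or a cluster id in ``[0, n_clusters)`` in
    discovery order, aligned with the input point list.  ``is_core`` marks
    fixes whose dwell test was evaluated and passed; with hull-guided
    expansion on, interior cluster members are never queried and therefore
    never flagged core.  ``stats`` holds operation counters from the run
    (number of neighbourhood queries and candidate fixes inspected).
    """

    labels: np.ndarray
    is_core: np.ndarray
    n_clusters: int
    stats: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = (self.labels < NOISE) | (self.labels >= self.n_clusters)
        if np.any(bad):
            raise ValidationError("labels must be -1 or in [0, n_clusters)")
        if np.any(self.is_core & (self.labels == NOISE)):
            raise ValidationError("core points cannot be noise")


# ---------------------------------------------------------------------------
# definitional operations (public, list-of-TrackPoint level)


def temporal_neighborhood(
    p: TrackPoint, spatial_nbrs: Sequence[TrackPoint], max_interval_s: float
) -> list[TrackPoint]:
    """Maximal gap-bounded, time-contiguous run of the spatial neighbourhood
    containing ``p``.

    The spatial neighbourhood is sorted ascending by (t, id); the returned
    run is the maximal consecutive stretch containing ``p`` in which every
    gap between successive fixes is <= ``max_interval_s``.
    """
    nbrs = sorted(spatial_nbrs, key=lambda q: (q.t, q.id))
    try:
        j = next(i for i, q in enumerate(nbrs) if q.id == p.id)
    except StopIteration:
        raise ContractViolationError(
            "spatial neighbourhood must contain its own centre point"
        ) from None
    start = j
    while start > 0 and nbrs[start].t - nbrs[start - 1].t <= max_interval_s:
        start -= 1
    end = j
    while end < len(nbrs) - 1 and nbrs[end + 1].t - nbrs[end].t <= max_interval_s:
        end += 1
    return nbrs[start : end + 1]


def is_core(
    p: TrackPoint, t_nbrs: Sequence[TrackPoint], min_stay_s: float
) -> bool:
    """Dwell test: the temporal neighbourhood spans >= ``min_stay_s`` (inclusive)."""
    if not t_nbrs:
        raise ContractViolationError("temporal neighbourhood must be non-empty")
    ts = [q.t for q in t_nbrs]
    return (max(ts) - min(ts)) >= min_stay_s


# ---------------------------------------------------------------------------
# engine


class _Engine:
    """Vectorised clustering engine working in time-sorted position space."""

    def __init__(self, points: Sequence[TrackPoint], eps_km: float, use_quadtree: bool):
        n = len(points)
        ids = np.array([p.id for p in points], dtype=np.int64)
        if len(np.unique(ids)) != n:
            raise ValidationError("point ids must be unique")
        lats = np.array([p.pos.lat for p in points])
        lons = np.array([p.pos.lon for p in points])
        ts = np.array([p.t for p in points])
        check_antimeridian(lons)
        # work in ascending (t, id) order so neighbourhood index arrays are
        # automatically time-sorted with the documented tie-break
        self.order = np.lexsort((ids, ts))
        self.lat = lats[self.order]
        self.lon = lons[self.order]
        self.t = ts[self.order]
        self.pos_of_input = np.empty(n, dtype=np.intp)
        self.pos_of_input[self.order] = np.arange(n)
        #: input indices in ascending-id scan order
        self.scan_order = np.argsort(ids, kind="stable")
        self.eps = eps_km
        self.n = n
        self.tree = QuadTree(self.lat, self.lon) if (use_quadtree and n) else None
        self.n_queries = 0
        self.candidates_inspected = 0

    def query(self, pos: int) -> np.ndarray:
        """Sorted positions of all fixes within eps of fix ``pos``."""
        self.n_queries += 1
        c = GeoPoint(float(self.lat[pos]), float(self.lon[pos]))
        if self.tree is not None:
            hit, ncand = self.tree.query_radius(c, self.eps)
            self.candidates_inspected += ncand
            return hit
        d = haversine_km_arrays(c.lat, c.lon, self.lat, self.lon)
        self.candidates_inspected += self.n
        return np.flatnonzero(d <= self.eps)

    def run_containing(self, pos: int, nbrs: np.ndarray, max_interval: float) -> np.ndarray:
        """Maximal gap-bounded run of time-sorted ``nbrs`` containing ``pos``."""
        if len(nbrs) == 1:
            return nbrs
        j = int(np.searchsorted(nbrs, pos))
        gaps_bad = np.flatnonzero(np.diff(self.t[nbrs]) > max_interval)
        left = gaps_bad[gaps_bad < j]
        start = int(left[-1]) + 1 if len(left) else 0
        right = gaps_bad[gaps_bad >= j]
        end = int(right[0]) if len(right) else len(nbrs) - 1
        return nbrs[start : end + 1]

    def hull_frontier(self, members: np.ndarray) -> np.ndarray:
        """Convex-hull vertices of ``members``, projected locally about their centroid."""
        if len(members) <= 3:
            return members
        origin = GeoPoint(
            float(np.mean(self.lat[members])), float(np.mean(self.lon[members]))
        )
        x, y = project_local_arrays(self.lat[members], self.lon[members], origin)
        return members[convex_hull_indices(x, y)]


def _empty_labeling() -> ClusterLabeling:
    return ClusterLabeling(
        labels=np.empty(0, dtype=np.int64),
        is_core=np.empty(0, dtype=bool),
        n_clusters=0,
        stats={"n_queries": 0, "candidates_inspected": 0},
    )


def tdbscan(points: Sequence[TrackPoint], params: TDBSCANParams) -> ClusterLabeling:
    """Cluster tracking fixes by spatiotemporal density.

    Deterministic for a given input: unvisited fixes are seeded in ascending
    id order, expansion is FIFO, and border fixes reachable from two
    clusters keep the first label assigned.  Revisits of the same location
    separated in time by more than ``max_interval_s`` never share a cluster
    unless bridged by intermediate fixes.
    """
    if not isinstance(params, TDBSCANParams):
        raise ValidationError("params must be a TDBSCANParams")
    if len(points) == 0:
        return _empty_labeling()

    eng = _Engine(points, params.eps_km, params.use_quadtree)
    n = eng.n
    labels = np.full(n, NOISE, dtype=np.int64)
    visited = np.zeros(n, dtype=bool)
    core = np.zeros(n, dtype=bool)
    enqueued = np.zeros(n, dtype=bool)
    cid = 0

    def frontier_of(members: np.ndarray) -> np.ndarray:
        if len(members) == 0:
            return members
        return eng.hull_frontier(members) if params.use_hull else members

    for inp in eng.scan_order:
        pos = int(eng.pos_of_input[inp])
        if visited[pos]:
            continue
        visited[pos] = True
        nbrs = eng.query(pos)
        run = eng.run_containing(pos, nbrs, params.max_interval_s)
        if eng.t[run[-1]] - eng.t[run[0]] < params.min_stay_s:
            continue  # not core; stays noise unless claimed as border later
        core[pos] = True
        labels[pos] = cid
        enqueued[pos] = True
        new = run[labels[run] == NOISE]
        labels[new] = cid
        visited[new] = True
        queue: deque[int] = deque()
        for f in frontier_of(new):
            if not enqueued[f]:
                enqueued[f] = True
                queue.append(int(f))
        while queue:
            q = queue.popleft()
            visited[q] = True
            qn = eng.query(q)
            qrun = eng.run_containing(q, qn, params.max_interval_s)
            if eng.t[qrun[-1]] - eng.t[qrun[0]] < params.min_stay_s:
                continue  # border fix: labelled, not expanded
            core[q] = True
            qnew = qrun[labels[qrun] == NOISE]
            labels[qnew] = cid
            visited[qnew] = True
            for f in frontier_of(qnew):
                if not enqueued[f]:
                    enqueued[f] = True
                    queue.append(int(f))
        cid += 1

    return ClusterLabeling(
        labels=labels[eng.pos_of_input],
        is_core=core[eng.pos_of_input],
        n_clusters=cid,
        stats={
            "n_queries": eng.n_queries,
            "candidates_inspected": eng.candidates_inspected,
        },
    )


def dbscan_baseline(
    points: Sequence[TrackPoint],
    eps_km: float,
    min_pts: int,
    use_quadtree: bool = True,
) -> ClusterLabeling:
    """Classic (purely spatial) DBSCAN with the haversine metric.

    Core test: at least ``min_pts`` fixes (the fix itself included) within
    ``eps_km``.  Deterministic under ascending-id scan order.  Serves as the
    comparison baseline that merges interannual revisits of a site into one
    cluster, the failure mode the temporal variant is designed to avoid.
    """
    if not (math.isfinite(eps_km) and eps_km > 0):
        raise ValidationError("eps_km must be > 0")
    if min_pts < 1:
        raise ValidationError("min_pts must be >= 1")
    if len(points) == 0:
        return _empty_labeling()

    eng = _Engine(points, eps_km, use_quadtree)
    n = eng.n
    labels = np.full(n, NOISE, dtype=np.int64)
    visited = np.zeros(n, dtype=bool)
    core = np.zeros(n, dtype=bool)
    enqueued = np.zeros(n, dtype=bool)
    cid = 0

    for inp in eng.scan_order:
        pos = int(eng.pos_of_input[inp])
        if visited[pos]:
            continue
        visited[pos] = True
        nbrs = eng.query(pos)
        if len(nbrs) < min_pts:
            continue
        core[pos] = True
        labels[pos] = cid
        enqueued[pos] = True
        queue: deque[int] = deque()
        new = nbrs[labels[nbrs] == NOISE]
        labels[new] = cid
        for f in new:
            if not enqueued[f]:
                enqueued[f] = True
                queue.append(int(f))
        while queue:
            q = queue.popleft()
            if visited[q]:
                continue
            visited[q] = True
            qn = eng.query(q)
            if len(qn) < min_pts:
                continue
            core[q] = True
            qnew = qn[labels[qn] == NOISE]
            labels[qnew] = cid
            for f in qnew:
                if not enqueued[f]:
                    enqueued[f] = True
                    queue.append(int(f))
        cid += 1

    return ClusterLabeling(
        labels=labels[eng.pos_of_input],
        is_core=core[eng.pos_of_input],
        n_clusters=cid,
        stats={
            "n_queries": eng.n_queries,
            "candidates_inspected": eng.candidates_inspected,
        },
    )
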