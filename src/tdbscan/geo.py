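"""Geometric substrate: great-circle distance, local planar projection,
quadtree spatial index, and Graham-scan convex hull.

All geographic coordinates are WGS84 decimal degrees, internally ordered
(lat, lon).  Distances are kilometres on a sphere of radius 6371.0 km
(the standard mean Earth radius).  Planar coordinates are kilometres east/
north of a reference origin under a local equirectangular projection,
which at the <= 25 km neighbourhood scales used here distorts distances
by well under 1%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np

from .errors import UnsupportedRegionError, ValidationError

EARTH_RADIUS_KM = 6371.0
#: Length of one degree of a great circle: 2*pi*R/360 ~ 111.195 km/deg.
KM_PER_DEG = math.pi * EARTH_RADIUS_KM / 180.0

__all__ = [
    "EARTH_RADIUS_KM",
    "KM_PER_DEG",
    "GeoPoint",
    "PlanarPoint",
    "QuadTree",
    "haversine_km",
    "project_local",
    "quadtree_build",
    "radius_query",
    "convex_hull",
    "convex_hull_indices",
]


@dataclass(frozen=True)
class GeoPoint:
    """A geographic position in decimal degrees (WGS84)."""

    lat: float
    lon: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.lat) and math.isfinite(self.lon)):
            raise ValidationError(f"non-finite coordinates ({self.lat}, {self.lon})")
        if not -90.0 <= self.lat <= 90.0:
            raise ValidationError(f"latitude {self.lat} outside [-90, 90]")
        if not -180.0 <= self.lon <= 180.0:
            raise ValidationError(f"longitude {self.lon} outside [-180, 180]")


class PlanarPoint(NamedTuple):
    """Kilometres east (x) / north (y) of a projection origin."""

    x: float
    y: float


# ---------------------------------------------------------------------------
# distance


def haversine_km(a: GeoPoint, b: GeoPoint) -> float:
    """Great-circle distance between two points in kilometres.

    Symmetric, non-negative, and zero iff the coordinates are identical.
    """
    lat1, lon1 = math.radians(a.lat), math.radians(a.lon)
    lat2, lon2 = math.radians(b.lat), math.radians(b.lon)
    s = (
        math.sin((lat2 - lat1) / 2.0) ** 2
        + math.cos(lat1) * math.cos(lat2) * math.sin((lon2 - lon1) / 2.0) ** 2
    )
    return 2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(s)))


def haversine_km_arrays(
    lat0: float, lon0: float, lats: np.ndarray, lons: np.ndarray
) -> np.ndarray:
    """Vectorised haversine from one point to many (degrees in, km out)."""
    p0, l0 = math.radians(lat0), math.radians(lon0)
    p = np.radians(lats)
    l = np.radians(lons)
    s = np.sin((p - p0) / 2.0) ** 2 + math.cos(p0) * np.cos(p) * np.sin(
        (l - l0) / 2.0
    ) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.minimum(1.0, np.sqrt(s)))


# ---------------------------------------------------------------------------
# local planar projection


def project_local_arrays(
    lats: np.ndarray, lons: np.ndarray, origin: GeoPoint
) -> tuple[np.ndarray, np.ndarray]:
    """Equirectangular projection to km east/north of ``origin``."""
    coslat = math.cos(math.radians(origin.lat))
    x = (np.asarray(lons, dtype=float) - origin.lon) * coslat * KM_PER_DEG
    y = (np.asarray(lats, dtype=float) - origin.lat) * KM_PER_DEG
    return x, y


def project_local(points: Sequence[GeoPoint], origin: GeoPoint) -> list[PlanarPoint]:
    """Project points onto a local plane centred on ``origin``.

    The origin maps to (0, 0).  Intended for neighbourhood-scale geometry
    (convex hulls, dispersion sums) where the flat-Earth error is negligible.
    """
    if len(points) == 0:
        raise ValidationError("project_local requires a non-empty point list")
    lats = np.array([p.lat for p in points])
    lons = np.array([p.lon for p in points])
    x, y = project_local_arrays(lats, lons, origin)
    return [PlanarPoint(float(xi), float(yi)) for xi, yi in zip(x, y)]


def unproject_local(x: float, y: float, origin: GeoPoint) -> GeoPoint:
    """Inverse of :func:`project_local` for a single point."""
    coslat = math.cos(math.radians(origin.lat))
    return GeoPoint(
        lat=origin.lat + y / KM_PER_DEG,
        lon=origin.lon + x / (KM_PER_DEG * coslat),
    )


def check_antimeridian(lons: np.ndarray) -> None:
    """Reject datasets whose longitudinal extent implies an antimeridian crossing.

    The supported study regions (continental flyways) never span it; correct
    wraparound indexing is deliberately unsupported.
    """
    if len(lons) and (np.max(lons) - np.min(lons)) > 180.0:
        raise UnsupportedRegionError(
            "dataset spans more than 180 degrees of longitude; "
            "antimeridian-crossing data are not supported"
        )


# ---------------------------------------------------------------------------
# quadtree


class _Node:
    __slots__ = ("x0", "y0", "x1", "y1", "depth", "idx", "children")

    def __init__(self, x0, y0, x1, y1, depth, idx):
        self.x0, self.y0, self.x1, self.y1 = x0, y0, x1, y1
        self.depth = depth
        self.idx = idx  # indices of ALL points in this subtree
        self.children: list[_Node] | None = None


class QuadTree:
    """Point-region quadtree over (lon, lat) with exact radius queries.

    Internal nodes keep the aggregated index array of their subtree so a
    query rectangle that fully contains a node is answered without
    descending.  Radius queries prune with a latitude-aware bounding box
    and then apply the exact haversine filter, so query results are
    independent of ``node_capacity`` / ``max_depth``.
    """

    def __init__(
        self,
        lats: np.ndarray,
        lons: np.ndarray,
        ids: np.ndarray | None = None,
        node_capacity: int = 16,
        max_depth: int = 24,
    ):
        if node_capacity < 1:
            raise ValidationError("node_capacity must be a positive integer")
        if max_depth < 1:
            raise ValidationError("max_depth must be a positive integer")
        self.lats = np.asarray(lats, dtype=float)
        self.lons = np.asarray(lons, dtype=float)
        n = len(self.lats)
        if len(self.lons) != n:
            raise ValidationError("lat/lon arrays must have equal length")
        self.ids = np.arange(n) if ids is None else np.asarray(ids)
        self.node_capacity = node_capacity
        self.max_depth = max_depth
        if n == 0:
            self.root = None
            return
        check_antimeridian(self.lons)
        pad = 1e-9  # expand so boundary points are strictly inside
        x0, x1 = float(self.lons.min()) - pad, float(self.lons.max()) + pad
        y0, y1 = float(self.lats.min()) - pad, float(self.lats.max()) + pad
        self.root = self._build(x0, y0, x1, y1, 0, np.arange(n))

    def _build(self, x0, y0, x1, y1, depth, idx) -> _Node:
        node = _Node(x0, y0, x1, y1, depth, idx)
        if len(idx) > self.node_capacity and depth < self.max_depth:
            xm, ym = (x0 + x1) / 2.0, (y0 + y1) / 2.0
            lx = self.lons[idx] < xm
            ly = self.lats[idx] < ym
            quads = (
                (idx[lx & ly], x0, y0, xm, ym),
                (idx[~lx & ly], xm, y0, x1, ym),
                (idx[lx & ~ly], x0, ym, xm, y1),
                (idx[~lx & ~ly], xm, ym, x1, y1),
            )
            node.children = [
                self._build(qx0, qy0, qx1, qy1, depth + 1, qidx)
                for qidx, qx0, qy0, qx1, qy1 in quads
                if len(qidx)
            ]
        return node

    def __len__(self) -> int:
        return len(self.lats)

    def depth(self) -> int:
        """Maximum node depth actually present in the tree."""
        if self.root is None:
            return 0

        def rec(node):
            if node.children is None:
                return node.depth
            return max(rec(c) for c in node.children)

        return rec(self.root)

    def _gather(self, bx0, by0, bx1, by1) -> list[np.ndarray]:
        """Index arrays of all candidate points whose node intersects the box."""
        out: list[np.ndarray] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            if node.x1 < bx0 or node.x0 > bx1 or node.y1 < by0 or node.y0 > by1:
                continue
            if bx0 <= node.x0 and node.x1 <= bx1 and by0 <= node.y0 and node.y1 <= by1:
                out.append(node.idx)  # fully contained: take whole subtree
            elif node.children is None:
                out.append(node.idx)
            else:
                stack.extend(node.children)
        return out

    def query_radius(self, center: GeoPoint, eps_km: float) -> tuple[np.ndarray, int]:
        """Exact radius query.

        Returns ``(indices, n_candidates)`` where ``indices`` are the sorted
        internal indices of points with haversine distance <= ``eps_km``
        (boundary inclusive) and ``n_candidates`` counts the points the
        bounding-box prune actually inspected with the exact filter.
        """
        if eps_km < 0:
            raise ValidationError("eps_km must be non-negative")
        if self.root is None:
            return np.empty(0, dtype=np.intp), 0
        dlat = eps_km / KM_PER_DEG
        if abs(center.lat) >= 89.0:
            bx0, bx1 = -180.0, 180.0
        else:
            dlon = eps_km / (KM_PER_DEG * math.cos(math.radians(center.lat)))
            bx0, bx1 = center.lon - dlon, center.lon + dlon
        by0, by1 = center.lat - dlat, center.lat + dlat
        chunks = self._gather(bx0, by0, bx1, by1)
        if not chunks:
            return np.empty(0, dtype=np.intp), 0
        cand = chunks[0] if len(chunks) == 1 else np.concatenate(chunks)
        d = haversine_km_arrays(
            center.lat, center.lon, self.lats[cand], self.lons[cand]
        )
        hit = cand[d <= eps_km]
        hit.sort()
        return hit, len(cand)


def quadtree_build(
    points: Sequence[GeoPoint],
    ids: Sequence[int] | None = None,
    node_capacity: int = 16,
    max_depth: int = 24,
) -> QuadTree:
    """Build a quadtree over a list of :class:`GeoPoint` (empty list allowed)."""
    lats = np.array([p.lat for p in points], dtype=float)
    lons = np.array([p.lon for p in points], dtype=float)
    idarr = None if ids is None else np.asarray(list(ids))
    return QuadTree(lats, lons, idarr, node_capacity=node_capacity, max_depth=max_depth)


def radius_query(tree: QuadTree, center: GeoPoint, eps_km: float) -> set[int]:
    """All point ids within ``eps_km`` of ``center`` (boundary inclusive)."""
    hit, _ = tree.query_radius(center, eps_km)
    return set(int(i) for i in tree.ids[hit])


# ---------------------------------------------------------------------------
# convex hull (Graham scan)


def _cross(ox, oy, ax, ay, bx, by) -> float:
    return (ax - ox) * (by - oy) - (ay - oy) * (bx - ox)


def convex_hull_indices(xs: np.ndarray, ys: np.ndarray) -> list[int]:
    """Graham scan over planar points given as parallel coordinate arrays.

    Returns indices of the strictly convex hull in counter-clockwise order,
    starting from the lowest-y (then lowest-x) point.  Duplicate coordinates
    keep their first index; collinear edge-interior points are dropped.
    Inputs of (deduplicated) size <= 2 are returned as-is.
    """
    n = len(xs)
    seen: dict[tuple[float, float], int] = {}
    for i in range(n):
        key = (float(xs[i]), float(ys[i]))
        if key not in seen:
            seen[key] = i
    uniq = sorted(seen.values(), key=lambda i: (ys[i], xs[i], i))
    if len(uniq) <= 2:
        return uniq
    p0 = uniq[0]
    x0, y0 = float(xs[p0]), float(ys[p0])

    def polar(i: int):
        dx = float(xs[i]) - x0
        dy = float(ys[i]) - y0
        return (math.atan2(dy, dx), dx * dx + dy * dy, i)

    rest = sorted(uniq[1:], key=polar)
    stack = [p0]
    for i in rest:
        while (
            len(stack) >= 2
            and _cross(
                xs[stack[-2]], ys[stack[-2]], xs[stack[-1]], ys[stack[-1]], xs[i], ys[i]
            )
            <= 0.0
        ):
            stack.pop()
        stack.append(i)
    return stack


def convex_hull(points: Iterable[tuple[float, float]]) -> list[PlanarPoint]:
    """Strictly convex hull of planar points, CCW from the lowest-(y, x) vertex."""
    pts = [PlanarPoint(float(x), float(y)) for x, y in points]
    if not pts:
        return []
    xs = np.array([p.x for p in pts])
    ys = np.array([p.y for p in pts])
    return [pts[i] for i in convex_hull_indices(xs, ys)]
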