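"""Clustering-quality and clustering-comparison metrics.

The Calinski–Harabasz (CH) index is the ratio of between-cluster to
within-cluster dispersion, each normalised by its degrees of freedom:

    CH = [ sum_j n_j |c_j - c|^2 / (k - 1) ] / [ sum_j sum_{x in C_j} |x - c_j|^2 / (n - k) ]

computed here in local planar kilometres (squared-degree dispersions would
mix unequal units across latitude).  Higher is better.

The *recognition difference rate* compares two labelings of the same fixes:
clusters are matched one-to-one by maximising total point overlap (optimal
assignment), noise is a reserved class matched to noise, and the rate is
the fraction of fixes whose matched label disagrees.  It is 0 exactly when
the two labelings induce the same partition, regardless of cluster
numbering, and it is symmetric in its arguments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .cluster import NOISE, ClusterLabeling, TrackPoint
from .errors import UndefinedMetricError, ValidationError
from .geo import GeoPoint, project_local_arrays

__all__ = [
    "CHResult",
    "ConfusionReport",
    "calinski_harabasz",
    "recognition_difference_rate",
    "confusion_report",
]


@dataclass(frozen=True)
class CHResult:
    """Calinski–Harabasz score with its dispersion components (km^2)."""

    ch: float
    k: int
    n: int
    between_ss: float
    within_ss: float


def _planar_coords(points, mask: np.ndarray) -> np.ndarray:
    lats = np.array([p.pos.lat for p in points])[mask]
    lons = np.array([p.pos.lon for p in points])[mask]
    origin = GeoPoint(float(lats.mean()), float(lons.mean()))
    x, y = project_local_arrays(lats, lons, origin)
    return np.column_stack([x, y])


def calinski_harabasz(
    points: list[TrackPoint],
    labeling: ClusterLabeling,
    include_noise: bool = False,
) -> CHResult:
    """CH index of a labeling, in local planar km about the dataset centroid.

    Noise fixes are excluded by default; with ``include_noise=True`` they are
    scored as one additional cluster.  Undefined (raises) when fewer than two
    clusters remain or when n <= k.
    """
    labels = np.asarray(labeling.labels)
    if len(labels) != len(points):
        raise ValidationError("labeling does not cover the point list")
    mask = np.ones(len(labels), dtype=bool) if include_noise else labels != NOISE
    if not mask.any():
        raise UndefinedMetricError("all points are noise; CH undefined")
    lab = labels[mask]
    uniq = np.unique(lab)
    k, n = len(uniq), int(mask.sum())
    if k < 2 or n <= k:
        raise UndefinedMetricError(f"CH requires 1 < k < n (got k={k}, n={n})")
    xy = _planar_coords(points, mask)
    overall = xy.mean(axis=0)
    between = 0.0
    within = 0.0
    for u in uniq:
        member = xy[lab == u]
        c = member.mean(axis=0)
        between += len(member) * float(np.sum((c - overall) ** 2))
        within += float(np.sum((member - c) ** 2))
    if within == 0.0:
        ch = math.inf
    else:
        ch = (between / (k - 1)) / (within / (n - k))
    return CHResult(ch=ch, k=k, n=n, between_ss=between, within_ss=within)


# ---------------------------------------------------------------------------
# labeling comparison


def _as_labels(obj) -> np.ndarray:
    if isinstance(obj, ClusterLabeling):
        return np.asarray(obj.labels)
    return np.asarray(obj)


def _contingency(a: np.ndarray, b: np.ndarray):
    ua = np.unique(a[a != NOISE])
    ub = np.unique(b[b != NOISE])
    m = np.zeros((len(ua), len(ub)), dtype=np.int64)
    ia = {u: i for i, u in enumerate(ua)}
    ib = {u: i for i, u in enumerate(ub)}
    for x, y in zip(a, b):
        if x != NOISE and y != NOISE:
            m[ia[x], ib[y]] += 1
    return ua, ub, m


def _match(ua, ub, m) -> list[tuple[int, int]]:
    """One-to-one cluster matching maximising total overlap (optimal assignment)."""
    if len(ua) == 0 or len(ub) == 0:
        return []
    rows, cols = linear_sum_assignment(-m)
    return [
        (int(ua[r]), int(ub[c])) for r, c in zip(rows, cols) if m[r, c] > 0
    ]


def recognition_difference_rate(a, b) -> float:
    """Fraction of fixes whose cluster assignment differs after optimal
    cluster matching, with noise as a reserved class.

    0 for identical partitions (any cluster renumbering), 1 when no fix
    agrees; a symmetric pseudo-metric on labelings modulo renaming.
    """
    la, lb = _as_labels(a), _as_labels(b)
    if len(la) != len(lb):
        raise ValidationError("labelings must cover the same point set")
    n = len(la)
    if n == 0:
        return 0.0
    ua, ub, m = _contingency(la, lb)
    agree = int(np.sum((la == NOISE) & (lb == NOISE)))
    ia = {u: i for i, u in enumerate(ua)}
    ib = {u: i for i, u in enumerate(ub)}
    for ca, cb in _match(ua, ub, m):
        agree += int(m[ia[ca], ib[cb]])
    return 1.0 - agree / n


@dataclass
class ConfusionReport:
    """Full contingency table between two labelings plus matched pairs.

    ``table`` rows are clusters of the first labeling (noise last), columns
    clusters of the second; entries count shared fixes.  ``jaccard`` maps
    each matched cluster pair to its Jaccard overlap.
    """

    table: pd.DataFrame
    matched: list[tuple[int, int]]
    jaccard: dict[tuple[int, int], float]


def confusion_report(a, b) -> ConfusionReport:
    """Contingency table, optimal matched pairs, and per-pair Jaccard indices."""
    la, lb = _as_labels(a), _as_labels(b)
    if len(la) != len(lb):
        raise ValidationError("labelings must cover the same point set")
    ua, ub, m = _contingency(la, lb)
    rows = list(ua) + [NOISE]
    cols = list(ub) + [NOISE]
    table = pd.DataFrame(0, index=rows, columns=cols, dtype=np.int64)
    for x, y in zip(la, lb):
        table.loc[x, y] += 1
    matched = _match(ua, ub, m)
    jaccard = {}
    for ca, cb in matched:
        na = int(np.sum(la == ca))
        nb = int(np.sum(lb == cb))
        inter = int(table.loc[ca, cb])
        jaccard[(ca, cb)] = inter / (na + nb - inter)
    return ConfusionReport(table=table, matched=matched, jaccard=jaccard)
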