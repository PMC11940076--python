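"""Seeded simulator of satellite-tracked migration tracks with ground truth.

The generator emulates the statistical structure of hourly-duty-cycle
waterbird telemetry: multi-day stopovers of within-site Gaussian wandering,
separated by fast straight-line flight legs, with fix intervals drawn
i.i.d. uniform between one and four hours (the tracker's voltage-dependent
duty cycle does not depend on behaviour, so flights are sampled at the
same rate).  An optional revisit schedule repeats the whole itinerary in
later years, reproducing interannual site fidelity.  Every run is fully
reproducible from a single RNG seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .cluster import TrackPoint
from .errors import ValidationError
from .geo import GeoPoint, KM_PER_DEG, haversine_km

__all__ = [
    "Site",
    "NoiseSpec",
    "SimConfig",
    "SiteVisit",
    "SyntheticTruth",
    "simulate_track",
    "scenario_library",
    "uniform_track_config",
]

#: 2023-01-01T00:00:00Z, the default simulated deployment epoch
DEFAULT_START_EPOCH = 1672531200.0
FLIGHT = -1
YEAR_S = 365.0 * 86400.0


@dataclass(frozen=True)
class Site:
    """A planted stopover: centre, stay length, and wandering radius."""

    center: GeoPoint
    stay_days: float
    radius_km: float = 3.0


@dataclass(frozen=True)
class NoiseSpec:
    """Uniform random fixes with no stopover structure (negative control)."""

    lat_range: tuple[float, float]
    lon_range: tuple[float, float]
    n_fixes: int


@dataclass(frozen=True)
class SimConfig:
    sites: tuple[Site, ...] = ()
    flight_speed_kmh: float = 60.0
    fix_interval_range_h: tuple[float, float] = (1.0, 4.0)
    jitter_km: float = 0.05
    seed: int = 0
    years: tuple[int, ...] = (0,)
    noise: NoiseSpec | None = None
    start_epoch: float = DEFAULT_START_EPOCH

    def __post_init__(self) -> None:
        lo, hi = self.fix_interval_range_h
        if not (0 < lo <= hi):
            raise ValidationError("fix_interval_range_h must satisfy 0 < min <= max")
        if self.flight_speed_kmh <= 0:
            raise ValidationError("flight_speed_kmh must be > 0")
        if self.jitter_km < 0:
            raise ValidationError("jitter_km must be >= 0")
        if (len(self.sites) == 0) == (self.noise is None):
            raise ValidationError(
                "exactly one of sites (>= 1) or a noise spec must be given"
            )
        for s in self.sites:
            if s.stay_days <= 0:
                raise ValidationError("stay_days must be > 0")
            if s.radius_km < 0:
                raise ValidationError("radius_km must be >= 0")
        if self.noise is not None and self.noise.n_fixes < 1:
            raise ValidationError("noise n_fixes must be >= 1")


@dataclass(frozen=True)
class SiteVisit:
    """Ground-truth record of one planted visit to a site."""

    site_index: int
    arrival: float  # first emitted fix of the stay
    departure: float  # last emitted fix of the stay
    center: GeoPoint


@dataclass
class SyntheticTruth:
    """Planted schedule: per-point visit label (-1 = flight) and visit list.

    Labels index *visits* in emission order; without a multi-year revisit
    schedule this coincides with the site index.
    """

    labels: np.ndarray
    visits: list[SiteVisit] = field(default_factory=list)


class _Emitter:
    def __init__(self, config: SimConfig):
        self.rng = np.random.default_rng(config.seed)
        self.cfg = config
        self.ts: list[float] = []
        self.lats: list[float] = []
        self.lons: list[float] = []
        self.labels: list[int] = []

    def next_interval_s(self) -> float:
        lo, hi = self.cfg.fix_interval_range_h
        return float(self.rng.uniform(lo, hi)) * 3600.0

    def emit(self, t: float, lat: float, lon: float, label: int) -> None:
        if self.cfg.jitter_km > 0:
            dx, dy = self.rng.normal(0.0, self.cfg.jitter_km, size=2)
            lat = lat + dy / KM_PER_DEG
            lon = lon + dx / (KM_PER_DEG * math.cos(math.radians(lat)))
        # whole-second timestamps: lossless through ISO 8601 text round-trips
        self.ts.append(float(round(t)))
        self.lats.append(float(lat))
        self.lons.append(float(lon))
        self.labels.append(label)


def simulate_track(config: SimConfig) -> tuple[list[TrackPoint], SyntheticTruth]:
    """Simulate one track; returns fixes (time-ordered, ids 0..n-1) and truth."""
    em = _Emitter(config)
    visits: list[SiteVisit] = []

    if config.noise is not None:
        spec = config.noise
        t = config.start_epoch
        for _ in range(spec.n_fixes):
            lat = float(em.rng.uniform(*spec.lat_range))
            lon = float(em.rng.uniform(*spec.lon_range))
            em.emit(t, lat, lon, FLIGHT)
            t += em.next_interval_s()
    else:
        visit_idx = 0
        for year in config.years:
            t = config.start_epoch + year * YEAR_S
            for si, site in enumerate(config.sites):
                stay_end = t + site.stay_days * 86400.0
                first = t
                while t < stay_end:
                    dx, dy = em.rng.normal(0.0, site.radius_km, size=2)
                    lat = site.center.lat + dy / KM_PER_DEG
                    lon = site.center.lon + dx / (
                        KM_PER_DEG * math.cos(math.radians(site.center.lat))
                    )
                    em.emit(t, lat, lon, visit_idx)
                    last = t
                    t += em.next_interval_s()
                visits.append(
                    SiteVisit(
                        site_index=si,
                        arrival=round(first),
                        departure=round(last),
                        center=site.center,
                    )
                )
                visit_idx += 1
                if si + 1 < len(config.sites):
                    nxt = config.sites[si + 1]
                    dist = haversine_km(site.center, nxt.center)
                    duration_s = dist / config.flight_speed_kmh * 3600.0
                    t0 = t
                    while t < t0 + duration_s:
                        frac = (t - t0) / duration_s
                        lat = site.center.lat + frac * (nxt.center.lat - site.center.lat)
                        lon = site.center.lon + frac * (nxt.center.lon - site.center.lon)
                        em.emit(t, lat, lon, FLIGHT)
                        t += em.next_interval_s()

    points = [
        TrackPoint(id=i, pos=GeoPoint(em.lats[i], em.lons[i]), t=em.ts[i])
        for i in range(len(em.ts))
    ]
    return points, SyntheticTruth(labels=np.array(em.labels), visits=visits)


def scenario_library() -> dict[str, SimConfig]:
    """Named simulation scenarios used throughout testing and validation.

    * ``two_stop_flyway`` — two 10-day stopovers ~1000 km apart on a flyway.
    * ``multi_stop_migration`` — six stopovers with stays 14, 18, 7, 9, 16
      and 7 days along a northward migration.
    * ``interannual_revisit`` — one site visited in two consecutive years.
    * ``dense_blob`` — a single long, densely sampled stopover (>= 10k
      fixes); stress test for hull-guided expansion.
    * ``uniform_noise`` — spatially uniform fixes, no stopovers.
    """
    return {
        "two_stop_flyway": SimConfig(
            sites=(
                Site(GeoPoint(30.0, 114.0), stay_days=10.0),
                Site(GeoPoint(39.0, 114.5), stay_days=10.0),
            )
        ),
        "multi_stop_migration": SimConfig(
            sites=tuple(
                Site(GeoPoint(29.0 + 5.0 * i, 113.0 + 1.0 * i), stay_days=d)
                for i, d in enumerate((14.0, 18.0, 7.0, 9.0, 16.0, 7.0))
            )
        ),
        "interannual_revisit": SimConfig(
            sites=(Site(GeoPoint(30.0, 114.0), stay_days=10.0),),
            years=(0, 1),
        ),
        "dense_blob": SimConfig(
            sites=(Site(GeoPoint(31.0, 115.0), stay_days=35.0, radius_km=5.0),),
            fix_interval_range_h=(0.05, 0.1),
        ),
        "uniform_noise": SimConfig(
            noise=NoiseSpec(lat_range=(25.0, 45.0), lon_range=(100.0, 120.0), n_fixes=600)
        ),
    }


def uniform_track_config(
    n_fixes: int, density_per_1000km2: float = 1.0, seed: int = 0
) -> SimConfig:
    """Uniform fixes at constant spatial density (region area grows with n).

    Used for scaling experiments: at constant density the expected
    neighbourhood population is independent of n.
    """
    area_km2 = n_fixes / density_per_1000km2 * 1000.0
    side_km = math.sqrt(area_km2)
    lat0 = 40.0
    dlat = side_km / KM_PER_DEG
    dlon = side_km / (KM_PER_DEG * math.cos(math.radians(lat0)))
    return SimConfig(
        noise=NoiseSpec(
            lat_range=(lat0 - dlat / 2, lat0 + dlat / 2),
            lon_range=(110.0 - dlon / 2, 110.0 + dlon / 2),
            n_fixes=n_fixes,
        ),
        seed=seed,
    )
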