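"""Core T-DBSCAN semantics: temporal neighbourhoods, dwell test, clustering,
optimization equivalence, and the DBSCAN baseline."""

from dataclasses import replace

import numpy as np
import pytest

from tdbscan import (
    GeoPoint,
    TDBSCANParams,
    TrackPoint,
    UnsupportedRegionError,
    ValidationError,
    dbscan_baseline,
    haversine_km,
    is_core,
    recognition_difference_rate,
    scenario_library,
    simulate_track,
    tdbscan,
    temporal_neighborhood,
)
from tdbscan.errors import ContractViolationError

from conftest import make_track

PARAMS = TDBSCANParams()  # eps 25 km, min_stay 72 h, max_interval 3 d


# ---------------------------------------------------------------------------
# temporal neighbourhood and dwell test


def test_temporal_run_breaks_at_large_gap():
    nbrs = make_track([0, 2, 4, 30, 32], 30.0, 114.0)
    p = nbrs[1]  # hour 2
    run = temporal_neighborhood(p, nbrs, max_interval_s=6 * 3600.0)
    assert [q.t / 3600 for q in run] == [0, 2, 4]


def test_temporal_run_singleton_and_isolated():
    p = make_track([5], 30.0, 114.0)[0]
    assert temporal_neighborhood(p, [p], 3600.0) == [p]
    nbrs = make_track([0, 100, 200], 30.0, 114.0)
    run = temporal_neighborhood(nbrs[1], nbrs, max_interval_s=3600.0)
    assert run == [nbrs[1]]  # every neighbour isolated in time


def test_temporal_run_must_contain_query_point():
    nbrs = make_track([0, 1, 2], 30.0, 114.0)
    outsider = TrackPoint(id=99, pos=GeoPoint(30.0, 114.0), t=10.0)
    with pytest.raises(ContractViolationError):
        temporal_neighborhood(outsider, nbrs, 3600.0)


@pytest.mark.parametrize(
    "span_h, expected", [(4, False), (80, True), (72, True)]  # boundary inclusive
)
def test_dwell_test_span_threshold(span_h, expected):
    nbrs = make_track([0, span_h / 2, span_h], 30.0, 114.0)
    assert is_core(nbrs[0], nbrs, min_stay_s=72 * 3600.0) is expected


def test_dwell_test_rejects_empty_neighbourhood():
    p = make_track([0], 30.0, 114.0)[0]
    with pytest.raises(ContractViolationError):
        is_core(p, [], 0.0)


# ---------------------------------------------------------------------------
# tdbscan behaviour


def test_empty_input_gives_zero_clusters():
    lab = tdbscan([], PARAMS)
    assert lab.n_clusters == 0
    assert len(lab.labels) == 0


def test_two_stopovers_with_flight_leg():
    """Two planted 10-day stopovers 1000 km apart -> 2 clusters; transit noise.

    Expectations frozen from the unoptimized reference mode (linear scans,
    full-frontier expansion); the optimized pipeline must agree exactly here.
    """
    pts, truth = simulate_track(scenario_library()["two_stop_flyway"])
    reference = tdbscan(pts, replace(PARAMS, use_quadtree=False, use_hull=False))
    assert reference.n_clusters == 2
    optimized = tdbscan(pts, PARAMS)
    assert np.array_equal(optimized.labels, reference.labels)
    # flight fixes beyond eps of both site centres can join no cluster
    centers = [GeoPoint(30.0, 114.0), GeoPoint(39.0, 114.5)]
    for i in np.flatnonzero(truth.labels == -1):
        if all(haversine_km(pts[i].pos, c) > PARAMS.eps_km for c in centers):
            assert reference.labels[i] == -1


def test_interannual_revisit_splits_into_two_clusters():
    pts, truth = simulate_track(scenario_library()["interannual_revisit"])
    lab = tdbscan(pts, PARAMS)
    assert lab.n_clusters == 2
    assert len(truth.visits) == 2
    assert truth.visits[0].center == truth.visits[1].center


def test_revisit_identical_coordinates_one_year_apart():
    """Two 10-day windows at the very same coordinates, a year apart -> k=2."""
    year_h = 365 * 24
    hours = list(range(0, 240, 2)) + [year_h + h for h in range(0, 240, 2)]
    pts = make_track(hours, 30.0, 114.0)
    lab = tdbscan(pts, PARAMS)
    assert lab.n_clusters == 2
    first = lab.labels[: len(hours) // 2]
    second = lab.labels[len(hours) // 2 :]
    assert len(set(first)) == 1 and len(set(second)) == 1
    assert first[0] != second[0]


def test_hull_restriction_reduces_queries_and_barely_changes_labels(rng):
    """Dense 2-D blob over 10 days: hull-on vs hull-off labels differ <= 1%."""
    cfg = replace(
        scenario_library()["dense_blob"],
        sites=(replace(scenario_library()["dense_blob"].sites[0], stay_days=10.0),),
        fix_interval_range_h=(0.5, 0.7),
        seed=9,
    )
    pts, _ = simulate_track(cfg)
    assert len(pts) >= 300
    on = tdbscan(pts, PARAMS)
    off = tdbscan(pts, replace(PARAMS, use_hull=False))
    assert on.stats["n_queries"] < off.stats["n_queries"]
    assert recognition_difference_rate(on, off) <= 0.01


def test_quadtree_equivalence_is_exact_on_every_scenario():
    for name, cfg in scenario_library().items():
        pts, _ = simulate_track(cfg)
        with_tree = tdbscan(pts, PARAMS)
        without = tdbscan(pts, replace(PARAMS, use_quadtree=False))
        assert np.array_equal(with_tree.labels, without.labels), name
        assert with_tree.n_clusters == without.n_clusters, name


def test_temporal_split_property_doubles_cluster_count():
    """Appending a +1-year copy of the data yields each cluster twice."""
    pts, _ = simulate_track(scenario_library()["two_stop_flyway"])
    lab = tdbscan(pts, PARAMS)
    shifted = [
        TrackPoint(id=p.id + len(pts), pos=p.pos, t=p.t + 365 * 86400.0) for p in pts
    ]
    lab2 = tdbscan(pts + shifted, PARAMS)
    assert lab2.n_clusters == 2 * lab.n_clusters
    # each original cluster appears twice: as itself and as its shifted copy
    orig = lab2.labels[: len(pts)]
    copy = lab2.labels[len(pts) :]
    assert np.array_equal(orig, lab.labels)
    size = lambda labels: sorted(
        int(np.sum(labels == c)) for c in set(labels) if c != -1
    )
    assert size(orig) == size(copy)


def test_core_partition_invariant_under_input_shuffle(rng):
    """Shuffled scan order only renumbers clusters and moves border fixes.

    Asserted with full-frontier expansion; the hull-restricted frontier is
    an order-dependent approximation by design.
    """
    pts, _ = simulate_track(scenario_library()["multi_stop_migration"])
    params = replace(PARAMS, use_hull=False)
    lab = tdbscan(pts, params)
    perm = rng.permutation(len(pts))
    shuffled = [TrackPoint(id=int(perm[i]), pos=p.pos, t=p.t) for i, p in enumerate(pts)]
    lab_s = tdbscan(shuffled, params)
    assert lab_s.n_clusters == lab.n_clusters
    # group core fixes (by list position, unchanged) into clusters
    def core_partition(l):
        groups = {}
        for i in np.flatnonzero(l.is_core):
            groups.setdefault(int(l.labels[i]), set()).add(int(i))
        return {frozenset(v) for v in groups.values()}

    assert core_partition(lab) == core_partition(lab_s)


def test_every_cluster_has_a_core_point_and_noise_is_never_core():
    pts, _ = simulate_track(scenario_library()["multi_stop_migration"])
    lab = tdbscan(pts, PARAMS)
    labels = np.asarray(lab.labels)
    for c in range(lab.n_clusters):
        members = labels == c
        assert members.sum() >= 1
        assert np.any(lab.is_core & members)
    assert not np.any(lab.is_core & (labels == -1))


def test_duplicate_fixes_are_legal_distinct_points():
    pts = make_track([0, 0, 30, 60, 80], 30.0, 114.0)
    lab = tdbscan(pts, PARAMS)
    assert len(lab.labels) == 5
    assert lab.n_clusters == 1


def test_invalid_params_and_regions_rejected():
    with pytest.raises(ValidationError):
        TDBSCANParams(eps_km=0.0)
    with pytest.raises(ValidationError):
        TDBSCANParams(max_interval_s=0.0)
    spanning = make_track([0, 1], [0.0, 0.0], [-179.0, 179.0])
    with pytest.raises(UnsupportedRegionError):
        tdbscan(spanning, PARAMS)


# ---------------------------------------------------------------------------
# DBSCAN baseline


def test_baseline_sparse_points_are_all_noise():
    pts = make_track([0, 1, 2], [30.0, 35.0, 40.0], 114.0)  # ~550 km apart
    lab = dbscan_baseline(pts, eps_km=25.0, min_pts=2)
    assert lab.n_clusters == 0
    assert np.all(lab.labels == -1)


def test_baseline_single_blob_is_one_cluster(rng):
    lats = 30.0 + rng.normal(0, 0.01, size=50)
    lons = 114.0 + rng.normal(0, 0.01, size=50)
    pts = make_track(range(50), lats, lons)
    lab = dbscan_baseline(pts, eps_km=50.0, min_pts=3)
    assert lab.n_clusters == 1


def test_baseline_matches_sklearn_dbscan(rng):
    from sklearn.cluster import DBSCAN

    from tdbscan import EARTH_RADIUS_KM

    # three well-separated blobs plus scattered noise
    lats, lons = [], []
    for clat, clon in ((30, 110), (33, 118), (40, 112)):
        lats += list(clat + rng.normal(0, 0.05, size=40))
        lons += list(clon + rng.normal(0, 0.05, size=40))
    lats += list(rng.uniform(25, 45, size=30))
    lons += list(rng.uniform(105, 125, size=30))
    pts = make_track(range(len(lats)), lats, lons)
    mine = dbscan_baseline(pts, eps_km=25.0, min_pts=5)
    sk = DBSCAN(
        eps=25.0 / EARTH_RADIUS_KM, min_samples=5, metric="haversine"
    ).fit(np.radians(np.column_stack([lats, lons])))
    assert recognition_difference_rate(mine.labels, sk.labels_) == 0.0
    assert mine.n_clusters == len(set(sk.labels_) - {-1})


def test_baseline_parameter_validation():
    with pytest.raises(ValidationError):
        dbscan_baseline([], eps_km=25.0, min_pts=0)
    with pytest.raises(ValidationError):
        dbscan_baseline([], eps_km=-1.0, min_pts=2)
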