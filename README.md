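# tdbscan

Spatiotemporal density clustering for identifying migratory-bird **stopover
sites** in satellite tracking data.

Satellite telemetry of migrating birds is irregular: fixes arrive every one
to four hours depending on tracker voltage, birds revisit the same wetlands
in different seasons and years, and flight legs thread long gaps between
multi-day stays. Classic DBSCAN, which clusters on spatial density alone,
merges every visit to a site — across months or years — into a single
cluster and cannot report when a bird arrived or how long it stayed. This
package implements **T-DBSCAN**, a temporal variant designed for exactly
this data, together with the evaluation metrics and a synthetic trajectory
simulator used to validate it. It is aimed at movement ecologists working
with tracking CSVs (timestamp, latitude, longitude).

## The algorithm

For a fix $a_i = (x_i, y_i, t_i)$ with spatial radius $\varepsilon$ (km,
haversine distance):

* **Spatial neighbourhood** $N_\varepsilon(a_i) = \{a_j : \mathrm{dist}(a_i, a_j) \le \varepsilon\}$.
* **Temporal neighbourhood** $N_t(a_i)$: sort $N_\varepsilon(a_i)$ by time
  and take the maximal consecutive run containing $a_i$ in which every gap
  between successive fixes is at most `MaxIntervalTime`.
* **Core object**: $a_i$ is core when
  $\max_{a_j, a_k \in N_t(a_i)} |t_j - t_k| \ge$ `MinStayTime` — a
  dwell-time test replacing DBSCAN's MinPts.

Clusters are the maximal temporally-density-connected sets; fixes in no
cluster are noise (flight legs, brief stops). A stay at the same
coordinates one year later starts a new cluster, because the year-long gap
breaks the temporal run. Reference parameters for large waterbirds:
$\varepsilon$ = 25 km, `MinStayTime` = 72 h, `MaxIntervalTime` = 3 d.

Two switchable optimizations accelerate the scan without changing its
semantics materially:

* a **quadtree** spatial index for the $\varepsilon$-radius queries —
  provably label-identical to brute-force scans, since an exact haversine
  filter follows the index prune; and
* **convex-hull-guided expansion** (Graham scan): only the hull vertices of
  each newly claimed temporal neighbourhood are queried further, skipping
  interior fixes. This is an approximation with a small, measurable
  labelling discrepancy (about 1% or less of fixes in the worst case).

The package also provides the Calinski–Harabasz index (computed in local
planar km), a *recognition difference rate* comparing two labelings after
optimal cluster matching, a classic DBSCAN baseline, stopover summaries
(centroid, arrival, departure, duration), and a seeded simulator of
migration tracks with ground truth.

## Worked example

Simulate a flyway with two planted 10-day stopovers about 1000 km apart,
cluster it with the default parameters, and compare against the spatial
baseline:

```sh
$ tdbscan simulate --scenario two_stop_flyway --out flyway.csv
195 fixes -> flyway.csv; truth -> flyway_truth.csv

$ tdbscan cluster --input flyway.csv --output-prefix flyway
2 stopover site(s), 6 noise fix(es) of 195 -> flyway_*

$ head -3 flyway_stopovers.csv
cluster_id,centroid_lat,centroid_lon,arrival_iso,departure_iso,duration_days,n_fixes
0,30.00329606914581,113.99135573732065,2023-01-01T00:00:00+00:00,2023-01-11T00:53:16+00:00,10.0,95
1,38.999169916607165,114.49706447818303,2023-01-11T18:36:21+00:00,2023-01-21T18:12:14+00:00,10.0,94
```

Both planted stopovers are recovered with their 10.0-day durations; the six
noise fixes are the flight leg between them. The run also writes
`flyway_labeled.csv` (input rows plus `cluster` and `is_core` columns),
`flyway_stopovers.geojson`, and `flyway_metrics.json`:

```json
{ "ch": 2605228.88, "n_clusters": 2, "n_noise": 6, "n_points": 195 }
```

The very large CH value reflects two tight 3-km-radius clusters separated
by 1000 km. On this single-season track the baseline agrees; the
algorithms diverge on multi-year data — on the `interannual_revisit`
scenario (`tdbscan compare`) T-DBSCAN reports two stopovers a year apart
where spatial DBSCAN merges them into one.

Other subcommands: `tdbscan evaluate` (difference rate, CH, confusion
table between two labelings) and `tdbscan simulate --config cfg.yaml` for
custom scenarios. All subcommands accept `--help`.

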