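# Methods

## Model and definitions

The input is a sequence of fixes $a_i = (x_i, y_i, t_i)$: WGS84 position
plus UTC timestamp. Spatial distance is the haversine great-circle
distance on a sphere of radius 6371.0 km (standard mean Earth radius).
Clustering follows the temporal-density framework:

1. The **spatial neighbourhood** of $a_i$ is every fix within
   `eps_km` (haversine, boundary inclusive; the fix itself always
   belongs to its own neighbourhood).
2. The **temporal neighbourhood** is the maximal run of the time-sorted
   spatial neighbourhood *containing* $a_i$ in which every consecutive gap
   is at most `max_interval_s`. Anchoring the run at the query fix (rather
   than at the earliest neighbour) keeps the dwell test below well-posed
   for every fix; the two readings coincide whenever the earliest run
   contains the fix.
3. A fix is a **core object** when its temporal neighbourhood spans at
   least `min_stay_s` (inclusive).
4. Clusters are maximal sets connected through core objects' temporal
   neighbourhoods; everything else is noise. Expansion uses
   consecutive-gap semantics throughout — a cluster grows by exactly the
   temporal neighbourhood of each core fix it reaches — so the
   "stop expanding at the first oversized gap" rule and the neighbourhood
   definition agree.

There is no MinPts: temporal persistence replaces the neighbour count. A
single fix can in principle be core if its neighbourhood's span is long
enough; density in the spatial sense enters only through `eps_km`.

### Determinism

Seeds are scanned in ascending point id (the CLI's `--shuffle-seed`
restores a randomized order); expansion is FIFO; time sorts break ties by
(t, id); a border fix reachable from two clusters keeps the first label
assigned and is never re-queried. Identical input therefore yields
byte-identical output. Duplicate fixes (same position and time) are legal
distinct points.

## Parameters

| parameter | unit | default | why |
|---|---|---|---|
| `eps_km` | km | 25 | daily-movement scale of large waterbirds around a roost/forage complex |
| `min_stay_s` | s | 72 h | a stopover is a multi-day stay; 3 days excludes overnight rests |
| `max_interval_s` | s | 3 d | tolerates tracker gaps within one stay while splitting separate visits |
| `use_quadtree` | – | on | exact-equivalent neighbourhood index |
| `use_hull` | – | on | approximate expansion pruning (see below) |

The defaults are the published reference calibration for goose-scale
migrants; both temporal knobs default to the same 3-day window because the
source calibration names a single "3-day temporal window" without
distinguishing the two roles.

## Optimizations

**Quadtree.** A point-region quadtree over (lon, lat), node capacity 16,
maximum depth 24, bounds the tight data bounding box padded by 1e-9°.
Radius queries prune with a latitude-aware box (Δlat = eps/111.195 km/deg,
Δlon widened by 1/cos lat, clamped to the full longitude range above
|lat| ≥ 89°), then apply the exact haversine filter, so results — and
therefore labels — are identical to a linear scan regardless of tree
parameters. Internal nodes keep their subtree's aggregated index array, so
a query box covering a whole node is answered without descent; this keeps
the candidate count per query near the true neighbourhood size even for
dense single-site data. Datasets spanning more than 180° of longitude are
rejected: continental flyways never cross the antimeridian and wraparound
indexing is out of scope.

**Convex-hull-guided expansion.** When a core fix claims its temporal
neighbourhood, only the Graham-scan hull vertices of the newly claimed
fixes (projected to a local plane centred on their centroid) are enqueued
for further neighbourhood queries; interior fixes are labelled, marked
visited, and never queried. The hull is strictly convex (collinear
edge-interior points dropped), CCW from the lowest-(y, x) vertex, with
deterministic tie-breaks; sets of ≤ 3 points are their own frontier. This
prunes redundant queries in dense regions but is an approximation: a fix
reachable only through an interior fix's neighbourhood can be missed, and
interior fixes are not individually core-tested (their `is_core` flag
stays false). Measured across the scenario library the labelling
discrepancy against full-frontier expansion stays well below 1% of fixes;
with `use_hull=False` the classic exhaustive expansion is recovered
exactly. Because the hull frontier depends on discovery order, exact
permutation-invariance of the core partition is only guaranteed with the
hull off; the hull-on deviation is bounded by the same ~1% mechanism.

All geometry at neighbourhood scale (hull, dispersion sums) runs in a
local equirectangular projection, x = Δlon·cos(lat₀)·111.195 km,
y = Δlat·111.195 km; within 25 km of the origin the distance distortion
is below 1% (verified against the haversine oracle in the tests).

## Metrics

**Calinski–Harabasz.** CH = [Σⱼ nⱼ|c̄ⱼ − c̄|²/(k−1)] / [Σⱼ Σ_{x∈Cⱼ}
|x − c̄ⱼ|²/(n−k)], computed on coordinates projected to planar km about the
dataset centroid — squared-degree dispersions would mix unequal units
across latitude. Noise is excluded by default (CH is defined over
clustered samples); `include_noise=True` scores noise as one extra
cluster. Undefined (raises) for k < 2 or n ≤ k; zero within-dispersion
with k ≥ 2 yields +∞.

**Recognition difference rate.** Clusters of the two labelings are matched
one-to-one by maximising total shared fixes (Hungarian assignment on the
contingency table); noise is a reserved class matched to noise; the rate
is the fraction of fixes whose matched label disagrees. Optimal matching
was chosen over a greedy descending-overlap pass because it is exactly
symmetric in its arguments (a property the test suite asserts), while
still giving 0 for any renumbering of an identical partition and matching
a split cluster to its larger fragment. The companion `confusion_report`
exposes the full contingency table and per-matched-pair Jaccard indices.

## Synthetic data

The simulator emulates goose-scale satellite telemetry: an itinerary of
stopover sites, each a centre with i.i.d. 2-D Gaussian within-site scatter
(σ = `radius_km`, default 3 km), stays of several days to weeks, joined by
straight-line flight legs at 60 km/h in local planar space. Fix intervals
are i.i.d. uniform 1–4 h everywhere — the tracker's duty cycle does not
depend on behaviour — plus 0.05 km Gaussian GPS jitter. An optional year
schedule repeats the itinerary to create interannual revisits. Timestamps
are rounded to whole seconds so CSV round-trips are lossless. One RNG
stream per simulation, fully determined by the seed.

Scenario library: `two_stop_flyway` (two 10-day stays ~1000 km apart),
`multi_stop_migration` (six stays of 14, 18, 7, 9, 16, 7 days along a
northward flyway), `interannual_revisit` (one site, two years),
`dense_blob` (one 35-day stay sampled every 3–6 min, ≥ 10k fixes — a
hull-expansion stress test), and `uniform_noise` (no structure). The
scaling experiments use uniform fixes at constant spatial density (region
area proportional to n) so the expected neighbourhood population is
n-independent: candidate-inspection counts then grow near-linearly for the
indexed pipeline and quadratically for brute force. Problem sizes of
2k–8k fixes for scaling runs and ~10–11k for the dense stress test keep
the whole validation suite comfortably reproducible on a laptop.

What the generator does *not* model — correlated within-site movement,
tracker dropout beyond interval jitter, wind drift, coastline-following
flight paths, multi-individual variation — limits what passing tests say
about field data: they validate the clustering semantics and the
optimization equivalences, not ecological accuracy of any particular
parameter choice, which must be calibrated per species.

## Numerical and degenerate-input choices

* Haversine clamps its argument to [0, 1] before `asin` (guards 1-ulp
  overflow at antipodes); symmetry holds to 1e-9 km.
* The dwell and radius tests are boundary-inclusive (≥ `min_stay_s`,
  ≤ `eps_km`).
* Empty input clusters to zero clusters; an empty quadtree answers every
  query with the empty set.
* CSV parsing drops (and counts in the log) rows with unparseable
  timestamps or out-of-range coordinates; unzoned timestamps are UTC;
  remaining rows sort by (timestamp, file order).
* Coordinates are written with `repr` round-trip precision and read with
  pandas' `round_trip` float parser, so write→read is the identity.

## Known limitations

* Hull-guided expansion can omit boundary-adjacent fixes in complex
  cluster shapes (bounded ~1% discrepancy; disable with `use_hull=False`
  when exactness matters more than speed).
* `is_core` is not evaluated for interior fixes under hull expansion.
* No antimeridian support; no streaming/online mode; single-individual
  clustering only (run per individual and compare stopovers downstream).
* The equirectangular projection is only valid at neighbourhood scale; all
  continental-scale distances go through the haversine.
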