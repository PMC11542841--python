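# Methods

## Problem and scope

The package estimates the personnel required for door-to-door community
health delivery in one CHW catchment at a time: a set of buildings, a
footpath network, and a depot (the community health site) from which a
walking health worker departs and to which they return each day. Two
intervention templates are modeled — a mass distribution campaign that
enters every building, and a proCCM program that visits only occupied
households — plus a `custom` mode where the caller supplies the target
subset and visit times. Follow-up visits, task seasonality, referral
logic and per-household demographics are deliberately out of scope: a
round is a fixed set of independent visits, and a month is an integer
number of identical rounds.

## Walking metric

All movement happens on the footpath graph. Buildings snap to their
Euclidean-nearest network node (ties to the lowest node id); pairwise
walking times are exact shortest paths (Dijkstra from every serviced
node, via networkx) divided by a single global walking speed, default
5 km/h. Times are real-valued minutes end to end — nothing is rounded
to integers before routing, which avoids an accumulation of rounding
error that integer-minute solvers introduce. The matrix is symmetric by
construction and satisfies the metric axioms; route geometries are
reconstructed from stored predecessor trees, so exported polylines
re-sum exactly to the matrix entries.

Snapping to nodes (rather than to interior points of edges) is a
simplification that is adequate at footpath densities where node
spacing is small relative to building spacing; it is the one deliberate
deviation from what road-routing engines do. Terrain, slope, season
and land cover are not modeled; the single-speed assumption means all
travel-time errors scale multiplicatively.

## Scenario draw

Statuses are assigned by exact-count sampling: exactly
`round_half_up(0.40 · n)` buildings become occupied households, chosen
uniformly without replacement, and exactly `round_half_up(0.20 · n_occ)`
of those get a patient. Exact counts (rather than independent
Bernoulli draws) keep the target count deterministic at fixed n, so the
service-time total is invariant across seeds and the occupancy
randomization analysis isolates *where* households are, not *how many*
there are. Uniform sampling makes the draw spatially uncorrelated by
construction; a Monte-Carlo test confirms the mean pairwise distance
among occupied buildings matches the all-building value.

Default parameters (all overridable in `ScenarioConfig`, YAML-loadable):
8 h workday (480 min), 20 workdays/month, 5 km/h, 40 % occupancy, 20 %
patients, 30 min long visits, 5 min short visits, 1 visit/month.

## Routing

Service times are folded into the travel matrix — arc cost
`i→j = t(i,j) + service(j)`, no service on arrival at the depot — so a
route's duration is a plain arc sum and the workday horizon applies to
travel and service jointly.

The solver is defined fully so results are reproducible:

* **Construction** (Solomon-style sequential cheapest insertion):
  routes open one at a time; each is seeded with the unrouted target
  farthest from the depot and grown by the feasible insertion with the
  smallest duration increase (ties: lower target id, then lower
  position), until nothing fits, then the next route opens.
* **Improvement**: best-improvement local search over relocate (intra-
  and inter-route), inter-route exchange, and intra-route 2-opt
  (travel symmetry makes segment reversal cost a four-term delta),
  applied one best move at a time until no move improves the total by
  more than 1e-9 min. Move evaluation is vectorized with numpy.
* **Restarts**: three construction+search passes; the first is fully
  deterministic, later ones draw the route seed uniformly from the five
  farthest unrouted targets using the caller's RNG. Best feasible
  result wins. A repair step re-inserts any leftover targets after
  compaction; if targets remain unplaced the solution is returned with
  `feasible=False` (infeasibility is a value, not an error).

`brute_force_solve` is the testing oracle: Held–Karp gives the optimal
order for every target subset, a set-partition dynamic program splits
targets into at most `n_units` horizon-feasible routes, both exact; it
refuses more than 9 targets. On randomized small instances the
heuristic has matched the oracle's objective and minimum fleet size in
every observed case; the test gates are ≤ 5 % optimality gap and ≥ 80 %
exact fleet agreement, which leave room for unlucky geometry.

## Fleet sizing

Two steps: (1) the grand tour — one walker, infinite horizon —
estimates total work; (2) the VRPTW is solved with
`m₀ = ceil(grand_tour / 480)` units, incrementing by one until
feasible. "Grand tour duration" includes service time: the folded
matrix makes travel+service the natural single quantity, and seeding
with pure travel would start the search far below any feasible size
(service alone is a lower bound on person-days: `ceil(Σ service / 480)`).
A target whose round trip plus service exceeds the workday raises an
error naming it; the increment search is capped at the target count.

The resulting count is a person-day count: days for one CHW, or CHWs
for one day — the two readings are interchangeable because units are
identical.

## Program arithmetic

Monthly requirements multiply the one-round plan by the visit frequency
rather than re-solving a month-long instance — rounds are identical by
assumption, so re-solving would change nothing but runtime. CHW head
count is `ceil(monthly person-days / workdays per month)`. The
sensitivity grid sweeps patient visit times 10–120 min (step 10),
non-patient 5–60 min (step 5) and four monthly frequencies, 576 cells,
with household statuses drawn once and held fixed across the grid so
cells differ only in the parameters; the frequency axis reuses each
(patient, non-patient) solve, since frequency enters only through the
monthly scaling. `monthly_requirement` warns outside the standard
{1, 2, 4} frequency set.

The occupancy-randomization analysis re-draws statuses with seeds
`master + i` (i from 0, master defaulting to the config seed, so the
first resample is the identity and must reproduce the initial estimate
exactly) and re-plans every catchment with geography and matrices
fixed.

## Synthetic geography

The generator emulates clustered rural settlement: cluster centers
uniform in a square extent, buildings Gaussian around a uniformly
chosen center (default sd 0.25 km), the depot at the center of the
largest cluster (the "village center" stand-in for a CHS). Footpaths
are the Delaunay triangulation of all nodes with edges longer than
twice the median pruned, re-connected by the triangulation's minimum
spanning tree — connected, planar (|E| ≤ 3|V|−6) and sparse, like real
footpath webs. Coordinates are planar km on a local tangent plane;
geographic input would be projected on read, and the GPX export maps
km to lon/lat with a fixed equirectangular scale.

Defaults (100 buildings, 4 clusters, 6 km extent) sit in the middle of
the order-of-magnitude spread real catchments show; test sweeps span
10–440 buildings. What the generator does **not** emulate: terrain and
rivers, path quality, irregular village shapes, and the possibility of
using paths outside the catchment boundary — so passing tests
demonstrate the correctness of the optimization machinery on plausible
geography, not calibrated accuracy for any real district.

## Numerical choices

* Feasibility and improvement tolerances: 1e-9 min; bookkeeping checks
  at 1e-6 min.
* `round_half_up` for the occupancy counts (so 10 buildings → exactly
  4 occupied → exactly 1 patient).
* Ceiling computations subtract 1e-9 before `ceil` to absorb float
  noise at exact multiples (474/480 → 1, 481/480 → 2).
* Ties in insertion cost break by lower target id then position; ties
  in argmin scans resolve to the first (deterministic) index.
* Degenerate geometry: fewer than 3 nodes, or collinear point sets,
  fall back from Delaunay to the complete graph before pruning;
  zero-length edges (coincident points) are dropped.
* All randomness flows through `numpy.random.default_rng` seeded from
  the scenario config; exports are byte-stable for fixed inputs.

## Problem sizes used in validation

The test suite validates the travel metric against Floyd–Warshall on
graphs up to ~50 nodes, routing against the exact oracle on 50
instances of ≤ 8 targets, the constraint invariants on 200 random
catchments of 10–300 buildings, the full 576-cell grid on a
50-building catchment, and 20 occupancy resamples over a ten-catchment
district of 80–440 buildings. The acceptance script plans a
ten-catchment district of 40–400 buildings (2,020 buildings total).
These sizes exercise every code path at desk scale; district-scale runs
(hundreds of catchments) are a matter of wall time, not algorithm
changes.

## Known limitations

* The heuristic carries no optimality certificate; fleet sizes can
  exceed the true minimum when the heuristic misses a tight packing
  (observed rarely, bounded by the ≥ 80 % agreement gate at small n).
* Single time window per day; no per-household availability windows.
* One global walking speed; no elevation or seasonal effects.
* Monthly scaling assumes identical, independent rounds — no follow-up
  visits or carry-over between rounds.
* The "few percent" robustness of district totals to the occupancy draw
  is partly integer granularity at small district sizes; very small
  districts show proportionally larger relative swings.
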