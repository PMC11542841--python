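# lastmile

Geographic micro-planning for door-to-door community health delivery.

Community health workers (CHWs) in rural districts walk footpath networks to
visit households — for mass distribution campaigns (bed nets, drugs,
vaccines, censuses: every building) or proactive community case management
(proCCM: every occupied household, on a monthly schedule). How many
person-days does a catchment need, and what should each day's route look
like? `lastmile` answers both from the catchment's geography alone: building
locations, a footpath network and the community health site (CHS) acting as
the depot.

## The model

1. **Walking metric.** Buildings snap to their nearest footpath node; exact
   shortest paths (Dijkstra from every serviced node) at a constant walking
   speed (default 5 km/h) give a symmetric travel-time matrix
   `t(i, j)` in minutes, with reconstructable route geometries.
2. **Scenario.** Each building gets a status by exact-count uniform
   sampling: 40 % occupied households, 20 % of those with a patient.
   Service times attach per status (30 min long visits, 5 min short ones).
   Mass campaigns target every building; proCCM only occupied households.
3. **Routing (VRPTW).** Service times are folded into the matrix
   (`arc(i→j) = t(i,j) + service(j)`) and a single-depot vehicle routing
   problem with one daily time window `[0, 480]` min is solved for a fixed
   number of walking units: sequential cheapest-insertion construction
   seeded at the farthest unrouted target, then best-improvement local
   search (relocate, inter-route exchange, intra-route 2-opt) with a fixed
   number of randomized restarts. Every route starts and ends at the depot;
   every target is served exactly once. An exact Held–Karp /
   set-partition oracle (`brute_force_solve`) covers instances up to 9
   targets for testing.
4. **Fleet sizing.** Person-days per catchment = the first feasible fleet
   size starting from `m₀ = ceil(grand-tour duration / 480 min)`, where the
   grand tour is the unconstrained one-walker route over all targets.
5. **Program arithmetic.** Monthly person-days scale with visit frequency;
   CHW head count = `ceil(monthly person-days / 20 workdays)`. Sensitivity
   grids sweep visit times (patient 10–120 min × non-patient 5–60 min) and
   frequency; robustness analysis re-randomizes which buildings are
   occupied and re-plans.

A built-in generator produces synthetic clustered settlements (villages as
Gaussian clusters, footpaths as a pruned Delaunay triangulation kept
connected by its minimum spanning tree), so the whole pipeline runs and is
tested without any external map data.

## Worked example

```sh
$ lastmile synth --n-buildings 80 --n-clusters 3 --seed 42 --out-dir geo
wrote geo/buildings.geojson and geo/paths.geojson (80 buildings, 194 footpath edges)

$ lastmile plan geo --seed 42 --intervention proccm --out-dir plan_pro
geo: 32 targets, 2 person-days, 28.7 km travel, travel share 52.6%, 1 CHW(s) at 1 visit(s)/month

$ lastmile plan geo --seed 42 --out-dir plan_mass
geo: 80 targets, 4 person-days, 56.9 km travel, travel share 36.3%, 1 CHW(s) at 1 visit(s)/month
```

Of the 80 buildings, 32 (40 %) are occupied households, so the proCCM round
visits 32 targets and fits in 2 person-days — one CHW covers the catchment
in two days, or two CHWs in one. The mass campaign must enter all 80
buildings and needs 4 person-days; because short 5-minute stops dominate,
more of the day is spent walking (travel share 36.3 % of work time, and
52.6 % under proCCM where the catchment is crossed for fewer stops).
`plan_pro/` contains the per-day schedules:

```
day,order,target_id,arrival_min,service_min,cumulative_min
0,1,78,0.491,5.000,5.491
0,2,63,6.075,30.000,36.075
...
```

plus the same itineraries as GPX tracks (for handheld navigation) and
GeoJSON routes, all byte-reproducible for a fixed seed. `lastmile
sensitivity` and `lastmile resample` run the visit-time grid and the
occupancy-robustness analysis; the same operations are available as library
functions (`lastmile.plan_catchment`, `lastmile.sensitivity_grid`, …).

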