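"""Synthetic clustered-settlement catchments for testing and simulation.

Rural CHW catchments in this setting are a handful of villages — tight
clusters of buildings — joined by a sparse footpath network, with one
community health site acting as the depot.  The generator emulates that
structure: cluster centers drawn uniformly in a square extent, buildings
scattered around their center with isotropic Gaussian dispersion, and a
footpath graph built as a Delaunay triangulation pruned of long edges and
re-augmented with minimum-spanning-tree edges so it stays connected.

Real catchments vary in area over orders of magnitude; the spec of a
synthetic one (building count, cluster count, extent, dispersion, seed)
is the ``SettlementSpec``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import Delaunay, QhullError

from .network import PathNetwork
from .scenario import Building

__all__ = ["SettlementSpec", "Catchment", "generate_settlement"]

DEPOT_ID = 0

#: Delaunay edges longer than this multiple of the median edge length are
#: pruned (then reconnected through the MST) — long triangulation chords
#: across empty country are not plausible footpaths.
_PRUNE_FACTOR = 2.0


@dataclass(frozen=True)
class SettlementSpec:
    """Parameters of a synthetic catchment."""

    n_buildings: int = 100
    n_clusters: int = 4
    extent_km: float = 6.0
    cluster_sd_km: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_buildings < 1:
            raise ValueError("n_buildings must be >= 1")
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if not self.extent_km > 0:
            raise ValueError("extent_km must be positive")
        if not self.cluster_sd_km > 0:
            raise ValueError("cluster_sd_km must be positive")


@dataclass
class Catchment:
    """Buildings, footpath network and depot of one CHW catchment.

    Every building id is itself a network node (buildings are generated
    on — or snapped to — the graph); the depot is node 0.
    """

    buildings: list[Building]
    network: PathNetwork
    depot: int = DEPOT_ID

    @property
    def n_buildings(self) -> int:
        return len(self.buildings)


def _edges_from_triangulation(coords: np.ndarray) -> set[tuple[int, int]]:
    """Delaunay edge set over coords; complete graph for degenerate input."""
    n = len(coords)
    if n < 3:
        return {(i, j) for i in range(n) for j in range(i + 1, n)}
    try:
        tri = Delaunay(coords)
    except QhullError:
        return {(i, j) for i in range(n) for j in range(i + 1, n)}
    edges: set[tuple[int, int]] = set()
    for simplex in tri.simplices:
        for a in range(3):
            u, v = int(simplex[a]), int(simplex[(a + 1) % 3])
            edges.add((min(u, v), max(u, v)))
    return edges


def _mst_edges(coords: np.ndarray, edges: set[tuple[int, int]],
               lengths: dict[tuple[int, int], float]) -> set[tuple[int, int]]:
    """Kruskal MST over the given edge set (sorted for determinism)."""
    parent = list(range(len(coords)))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    mst: set[tuple[int, int]] = set()
    for (u, v) in sorted(edges, key=lambda e: (lengths[e], e)):
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv
            mst.add((u, v))
    return mst


def generate_settlement(spec: SettlementSpec) -> Catchment:
    """Generate a synthetic clustered settlement. Deterministic per seed.

    Cluster centers are uniform in the square extent; buildings scatter
    around a uniformly chosen center with the stated dispersion.  The
    depot sits at the center of the largest cluster (the "village
    center" stand-in for a community health site).  Footpaths are the
    Delaunay triangulation of all nodes, pruned of edges longer than
    twice the median edge length and re-augmented with MST edges, so the
    network is sparse, planar and connected.
    """
    rng = np.random.default_rng(spec.seed)
    centers = rng.uniform(0.0, spec.extent_km, size=(spec.n_clusters, 2))
    labels = rng.integers(0, spec.n_clusters, size=spec.n_buildings)
    offsets = rng.normal(0.0, spec.cluster_sd_km, size=(spec.n_buildings, 2))
    bld_xy = centers[labels] + offsets

    counts = np.bincount(labels, minlength=spec.n_clusters)
    largest = int(np.argmax(counts))  # ties -> lowest cluster index
    depot_xy = centers[largest]

    # node 0 = depot, nodes 1..n = buildings
    coords = np.vstack([depot_xy[None, :], bld_xy])
    edge_set = _edges_from_triangulation(coords)
    lengths = {
        (u, v): float(np.hypot(*(coords[u] - coords[v]))) for (u, v) in edge_set
    }
    # coincident points would create zero-length edges; drop them
    edge_set = {e for e in edge_set if lengths[e] > 0.0}

    if edge_set:
        med = float(np.median([lengths[e] for e in edge_set]))
        kept = {e for e in edge_set if lengths[e] <= _PRUNE_FACTOR * med}
        kept |= _mst_edges(coords, edge_set, lengths)
    else:
        kept = set()

    nodes = {i: (float(coords[i, 0]), float(coords[i, 1])) for i in range(len(coords))}
    network = PathNetwork(
        nodes=nodes,
        edges=[(u, v, lengths[(u, v)]) for (u, v) in sorted(kept)],
    )
    buildings = [
        Building(id=i + 1, coordinates=(float(bld_xy[i, 0]), float(bld_xy[i, 1])))
        for i in range(spec.n_buildings)
    ]
    return Catchment(buildings=buildings, network=network, depot=DEPOT_ID)
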