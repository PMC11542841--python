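"""Walking travel-time metric over a footpath network.

Buildings are snapped to their nearest network node and pairwise walking
times are obtained by exact shortest paths (Dijkstra from every serviced
node) at a single global walking speed.  Times are kept as real-valued
minutes throughout; no integerization happens before routing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = [
    "PathNetwork",
    "TravelTimeMatrix",
    "EmptyNetworkError",
    "DisconnectedNetworkError",
    "snap_points",
    "travel_time_matrix",
    "route_geometry",
]


class EmptyNetworkError(ValueError):
    """Raised when geography contains no usable footpath network."""


class DisconnectedNetworkError(ValueError):
    """Raised when a serviced point cannot be reached on foot."""


@dataclass
class PathNetwork:
    """Undirected weighted graph of footpath segments.

    Parameters
    ----------
    nodes
        Mapping node id -> (x, y) planar coordinates in km.
    edges
        Iterable of (u, v, length_km) with positive lengths and no
        self-loops.
    """

    nodes: dict[int, tuple[float, float]]
    edges: list[tuple[int, int, float]]
    graph: nx.Graph = field(init=False, repr=False)

    def __post_init__(self) -> None:
        g = nx.Graph()
        for nid, xy in self.nodes.items():
            g.add_node(nid, x=float(xy[0]), y=float(xy[1]))
        for u, v, length in self.edges:
            if u == v:
                raise ValueError(f"self-loop edge at node {u}")
            if not length > 0:
                raise ValueError(f"non-positive edge length on ({u}, {v})")
            if u not in self.nodes or v not in self.nodes:
                raise ValueError(f"edge ({u}, {v}) references unknown node")
            g.add_edge(u, v, length_km=float(length))
        self.graph = g

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def total_length_km(self) -> float:
        return float(sum(d["length_km"] for _, _, d in self.graph.edges(data=True)))

    def coords(self, node: int) -> tuple[float, float]:
        d = self.graph.nodes[node]
        return (d["x"], d["y"])

    def is_connected(self) -> bool:
        return self.n_nodes > 0 and nx.is_connected(self.graph)


@dataclass
class TravelTimeMatrix:
    """Pairwise walking minutes between the depot and every building.

    ``point_ids`` orders the rows/columns with the depot first.  The
    predecessor store retains, for every source point, enough of the
    Dijkstra tree to reconstruct a shortest path to any node.
    """

    point_ids: list[int]
    minutes: np.ndarray
    speed_kmh: float
    network: PathNetwork
    snapped: dict[int, int]           # point id -> network node id
    _pred: dict[int, dict[int, int]]  # source node -> {node: predecessor}

    @property
    def n_points(self) -> int:
        return len(self.point_ids)

    def index_of(self, point_id: int) -> int:
        return self.point_ids.index(point_id)


def snap_points(catchment) -> dict[int, int]:
    """Map every building (and the depot) to its Euclidean-nearest node.

    Ties are broken by the lowest node id.  Deterministic.
    """
    net = catchment.network
    if net.n_nodes == 0:
        raise EmptyNetworkError("cannot snap points: network has no nodes")
    node_ids = sorted(net.nodes)
    node_xy = np.array([net.nodes[n] for n in node_ids], dtype=float)
    mapping: dict[int, int] = {}
    points = [(catchment.depot, net.nodes[catchment.depot])] if catchment.depot in net.nodes else []
    if not points:
        raise EmptyNetworkError("depot is not a network node")
    mapping[catchment.depot] = catchment.depot
    for b in catchment.buildings:
        d2 = np.sum((node_xy - np.asarray(b.coordinates, dtype=float)) ** 2, axis=1)
        # argmin returns the first minimum; node_ids is sorted, so ties
        # resolve to the lowest node id.
        mapping[b.id] = node_ids[int(np.argmin(d2))]
    return mapping


def travel_time_matrix(catchment, speed_kmh: float) -> TravelTimeMatrix:
    """All-pairs walking minutes between depot and buildings.

    minutes[i][j] = shortest-path km between the snapped nodes of points
    i and j, divided by ``speed_kmh``, times 60.  Exact Dijkstra from
    each serviced node.
    """
    if not speed_kmh > 0:
        raise ValueError("walking speed must be positive")
    snapped = snap_points(catchment)
    point_ids = [catchment.depot] + sorted(b.id for b in catchment.buildings)
    nodes_needed = sorted(set(snapped.values()))
    g = catchment.network.graph

    dist: dict[int, dict[int, float]] = {}
    pred: dict[int, dict[int, int]] = {}
    for src in nodes_needed:
        p, d = nx.dijkstra_predecessor_and_distance(g, src, weight="length_km")
        dist[src] = d
        # keep one deterministic predecessor per node
        pred[src] = {n: min(ps) for n, ps in p.items() if ps}

    n = len(point_ids)
    minutes = np.zeros((n, n), dtype=float)
    for i, pi in enumerate(point_ids):
        di = dist[snapped[pi]]
        for j, pj in enumerate(point_ids):
            nj = snapped[pj]
            if nj not in di:
                raise DisconnectedNetworkError(
                    f"point {pj} (node {nj}) is unreachable from point {pi}"
                )
            minutes[i, j] = di[nj] / speed_kmh * 60.0
    return TravelTimeMatrix(
        point_ids=point_ids,
        minutes=minutes,
        speed_kmh=float(speed_kmh),
        network=catchment.network,
        snapped=snapped,
        _pred=pred,
    )


def route_geometry(matrix: TravelTimeMatrix, i: int, j: int) -> list[tuple[float, float]]:
    """Node coordinate sequence of one shortest path between points i and j.

    ``i`` and ``j`` are matrix indices (0 = depot).  The summed edge
    length of the returned polyline, divided by the walking speed,
    equals ``minutes[i][j]``.
    """
    n = matrix.n_points
    if not (0 <= i < n and 0 <= j < n):
        raise IndexError(f"point index out of range: ({i}, {j})")
    src = matrix.snapped[matrix.point_ids[i]]
    dst = matrix.snapped[matrix.point_ids[j]]
    if src == dst:
        return [matrix.network.coords(src)]
    pred = matrix._pred[src]
    seq = [dst]
    node = dst
    while node != src:
        node = pred[node]
        seq.append(node)
    seq.reverse()
    return [matrix.network.coords(n_) for n_ in seq]


def path_length_km(matrix: TravelTimeMatrix, i: int, j: int) -> float:
    """Length in km of the reconstructed shortest path between points i, j."""
    coords = np.asarray(route_geometry(matrix, i, j), dtype=float)
    if len(coords) < 2:
        return 0.0
    return float(np.sum(np.hypot(*(np.diff(coords, axis=0).T))))
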