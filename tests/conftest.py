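import numpy as np
import pytest

from lastmile.network import PathNetwork
from lastmile.scenario import Building
from lastmile.synthetic_geography import Catchment
from lastmile.vrptw import RoutingInstance


def line_catchment(positions_km, depot_at=0.0):
    """Catchment whose nodes lie on a line; depot node 0 at depot_at.

    ``positions_km`` are building positions along the x-axis; edges join
    consecutive nodes so shortest paths are forced.
    """
    nodes = {0: (float(depot_at), 0.0)}
    buildings = []
    for k, x in enumerate(positions_km, start=1):
        nodes[k] = (float(x), 0.0)
        buildings.append(Building(id=k, coordinates=(float(x), 0.0)))
    order = sorted(nodes, key=lambda n: (nodes[n][0], n))
    edges = []
    for a, b in zip(order, order[1:]):
        d = abs(nodes[a][0] - nodes[b][0])
        if d > 0:
            edges.append((a, b, d))
    net = PathNetwork(nodes=nodes, edges=edges)
    return Catchment(buildings=buildings, network=net, depot=0)


def euclidean_instance(xy, service, horizon=480.0, n_units=1, speed_kmh=5.0):
    """RoutingInstance from planar coordinates; row 0 is the depot."""
    xy = np.asarray(xy, dtype=float)
    d = np.hypot(xy[:, None, 0] - xy[None, :, 0],
                 xy[:, None, 1] - xy[None, :, 1]) / speed_kmh * 60.0
    s = np.concatenate([[0.0], np.asarray(service, dtype=float)])
    return RoutingInstance(d, s, horizon_min=horizon, n_units=n_units,
                           speed_kmh=speed_kmh)


def random_instance(rng, m=None, horizon=480.0, n_units=None,
                    extent_km=3.0, services=(5.0, 30.0)):
    """Random workday-scale instance with <= 8 targets."""
    if m is None:
        m = int(rng.integers(2, 9))
    if n_units is None:
        n_units = int(rng.integers(1, 4))
    xy = rng.uniform(0.0, extent_km, size=(m + 1, 2))
    svc = rng.choice(services, size=m)
    return euclidean_instance(xy, svc, horizon=horizon, n_units=n_units)


@pytest.fixture
def ten_buildings():
    """Ten buildings on a short line: the canonical arithmetic fixture."""
    return line_catchment([0.1 * k for k in range(1, 11)])
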