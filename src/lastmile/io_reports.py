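"""Reading and writing geography, plans and itineraries.

Geography travels as two GeoJSON files: a Point FeatureCollection for
buildings plus the depot, and a LineString FeatureCollection for
footpath edges carrying a ``length_km`` property.  Synthetic geography
lives on a local planar frame in km (declared via a ``crs_note``
property); itinerary exports convert to lon/lat with a fixed
equirectangular scale so GPX consumers get valid coordinates.

Exports are byte-stable for a fixed input: ordering is canonical and
floats are serialized with repr.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from xml.etree import ElementTree as ET

from .network import DisconnectedNetworkError, PathNetwork, TravelTimeMatrix, route_geometry
from .scenario import Building
from .synthetic_geography import Catchment

__all__ = [
    "MalformedGeographyError",
    "MissingDepotError",
    "write_geography",
    "read_geography",
    "export_itineraries",
    "write_matrix_csv",
]

BUILDINGS_FILE = "buildings.geojson"
PATHS_FILE = "paths.geojson"

# planar km -> pseudo lon/lat near the equator, for GPX/GeoJSON validity
_KM_PER_DEG_LON = 111.320
_KM_PER_DEG_LAT = 110.574

_DAY_START_MIN = 8 * 60  # nominal 08:00 departure for GPX timestamps


class MalformedGeographyError(ValueError):
    """Geography files exist but do not parse into a valid catchment."""


class MissingDepotError(MalformedGeographyError):
    """No feature with role 'depot' in the point collection."""


def _km_to_lonlat(x_km: float, y_km: float) -> tuple[float, float]:
    return (x_km / _KM_PER_DEG_LON, y_km / _KM_PER_DEG_LAT)


def write_geography(catchment: Catchment, out_dir) -> tuple[Path, Path]:
    """Write a catchment as two GeoJSON files; byte-stable per input."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    net = catchment.network

    feats = [{
        "type": "Feature",
        "id": catchment.depot,
        "geometry": {"type": "Point",
                     "coordinates": list(net.coords(catchment.depot))},
        "properties": {"role": "depot"},
    }]
    for b in sorted(catchment.buildings, key=lambda b: b.id):
        feats.append({
            "type": "Feature",
            "id": b.id,
            "geometry": {"type": "Point", "coordinates": list(b.coordinates)},
            "properties": {"role": "building"},
        })
    points = {
        "type": "FeatureCollection",
        "crs_note": "local planar frame, units km",
        "features": feats,
    }

    lines = {
        "type": "FeatureCollection",
        "crs_note": "local planar frame, units km",
        "features": [
            {
                "type": "Feature",
                "geometry": {
                    "type": "LineString",
                    "coordinates": [list(net.coords(u)), list(net.coords(v))],
                },
                "properties": {
                    "u": u, "v": v,
                    "length_km": net.graph.edges[u, v]["length_km"],
                },
            }
            for u, v in sorted(tuple(sorted(e)) for e in net.graph.edges)
        ],
    }
    bp = out / BUILDINGS_FILE
    pp = out / PATHS_FILE
    bp.write_text(json.dumps(points, sort_keys=True, indent=1) + "\n")
    pp.write_text(json.dumps(lines, sort_keys=True, indent=1) + "\n")
    return bp, pp


def read_geography(path) -> Catchment:
    """Read the two-file GeoJSON geography dialect back into a Catchment.

    Raises ``MalformedGeographyError`` for unparseable input,
    ``MissingDepotError`` if no depot feature exists, and
    ``DisconnectedNetworkError`` if the footpath graph does not connect
    the serviced nodes.
    """
    d = Path(path)
    try:
        points = json.loads((d / BUILDINGS_FILE).read_text())
        lines = json.loads((d / PATHS_FILE).read_text())
    except FileNotFoundError as e:
        raise MalformedGeographyError(f"geography file missing: {e}") from e
    except json.JSONDecodeError as e:
        raise MalformedGeographyError(f"invalid JSON in geography: {e}") from e

    try:
        depot_id = None
        buildings: list[Building] = []
        node_coords: dict[int, tuple[float, float]] = {}
        for f in points["features"]:
            fid = int(f["id"])
            x, y = (float(c) for c in f["geometry"]["coordinates"])
            role = f["properties"].get("role", "building")
            node_coords[fid] = (x, y)
            if role == "depot":
                depot_id = fid
            else:
                buildings.append(Building(id=fid, coordinates=(x, y)))
        edges = []
        for f in lines["features"]:
            p = f["properties"]
            edges.append((int(p["u"]), int(p["v"]), float(p["length_km"])))
    except (KeyError, TypeError, ValueError) as e:
        raise MalformedGeographyError(f"unexpected geography structure: {e}") from e

    if depot_id is None:
        raise MissingDepotError("no feature with role 'depot'")
    if not buildings:
        raise MalformedGeographyError("geography contains no buildings")

    # edges may reference pure path nodes absent from the point file;
    # infer their coordinates from line endpoints
    for f in lines["features"]:
        p = f["properties"]
        cs = f["geometry"]["coordinates"]
        for nid, c in ((int(p["u"]), cs[0]), (int(p["v"]), cs[-1])):
            node_coords.setdefault(nid, (float(c[0]), float(c[1])))

    network = PathNetwork(nodes=node_coords, edges=edges)
    catchment = Catchment(buildings=buildings, network=network, depot=depot_id)
    if not network.is_connected():
        raise DisconnectedNetworkError("footpath network is not connected")
    return catchment


# ---------------------------------------------------------------------------
# itinerary export
# ---------------------------------------------------------------------------

def _day_polyline(itinerary, matrix: TravelTimeMatrix) -> list[tuple[float, float]]:
    pos = {pid: k for k, pid in enumerate(matrix.point_ids)}
    seq = [0] + [pos[p] for p in itinerary.visit_order] + [0]
    poly: list[tuple[float, float]] = []
    for a, b in zip(seq, seq[1:]):
        leg = route_geometry(matrix, a, b)
        if poly and leg and poly[-1] == leg[0]:
            leg = leg[1:]
        poly.extend(leg)
    return poly


def _fmt_time(minute_of_day: float) -> str:
    total = _DAY_START_MIN + minute_of_day
    h, rem = divmod(int(round(total * 60)), 3600)
    m, s = divmod(rem, 60)
    return f"2000-01-01T{h:02d}:{m:02d}:{s:02d}Z"


def export_itineraries(solution, matrix: TravelTimeMatrix, fmt: str, out_path) -> Path:
    """Export per-day itineraries as GPX 1.1, CSV, or GeoJSON.

    GPX: one track per person-day following the route polyline, plus a
    waypoint per stop (timestamps as offsets from a nominal 08:00
    start).  CSV: one row per stop with day, order, id, arrival minute,
    service minutes and cumulative minutes.  GeoJSON: a LineString per
    day and a Point per stop.  Byte-stable for fixed input.
    """
    if not solution.feasible:
        raise ValueError("refusing to export an infeasible solution")
    out = Path(out_path)
    out.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "csv":
        _export_csv(solution, out)
    elif fmt == "gpx":
        _export_gpx(solution, matrix, out)
    elif fmt == "geojson":
        _export_geojson(solution, matrix, out)
    else:
        raise ValueError(f"unknown export format: {fmt!r}")
    return out


def _export_csv(solution, out: Path) -> None:
    with open(out, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["day", "order", "target_id", "arrival_min",
                    "service_min", "cumulative_min"])
        for it in solution.itineraries:
            for k, pid in enumerate(it.visit_order):
                w.writerow([
                    it.unit_index, k + 1, pid,
                    f"{it.arrivals_min[k]:.3f}",
                    f"{it.departures_min[k] - it.arrivals_min[k]:.3f}",
                    f"{it.departures_min[k]:.3f}",
                ])


def _export_gpx(solution, matrix: TravelTimeMatrix, out: Path) -> None:
    gpx = ET.Element("gpx", {
        "version": "1.1",
        "creator": "lastmile",
        "xmlns": "http://www.topografix.com/GPX/1/1",
    })
    snap = matrix.snapped
    net = matrix.network
    for it in solution.itineraries:
        for k, pid in enumerate(it.visit_order):
            x, y = net.coords(snap[pid])
            lon, lat = _km_to_lonlat(x, y)
            wpt = ET.SubElement(gpx, "wpt",
                                {"lat": f"{lat:.8f}", "lon": f"{lon:.8f}"})
            ET.SubElement(wpt, "time").text = _fmt_time(it.arrivals_min[k])
            ET.SubElement(wpt, "name").text = f"day{it.unit_index}-stop{k + 1}-id{pid}"
        trk = ET.SubElement(gpx, "trk")
        ET.SubElement(trk, "name").text = f"day-{it.unit_index}"
        seg = ET.SubElement(trk, "trkseg")
        for x, y in _day_polyline(it, matrix):
            lon, lat = _km_to_lonlat(x, y)
            ET.SubElement(seg, "trkpt",
                          {"lat": f"{lat:.8f}", "lon": f"{lon:.8f}"})
    ET.indent(gpx)
    ET.ElementTree(gpx).write(out, encoding="unicode", xml_declaration=True)
    with open(out, "a") as fh:
        fh.write("\n")


def _export_geojson(solution, matrix: TravelTimeMatrix, out: Path) -> None:
    feats = []
    snap = matrix.snapped
    net = matrix.network
    for it in solution.itineraries:
        feats.append({
            "type": "Feature",
            "geometry": {
                "type": "LineString",
                "coordinates": [[x, y] for x, y in _day_polyline(it, matrix)],
            },
            "properties": {
                "kind": "route", "day": it.unit_index,
                "travel_min": it.travel_min, "service_min": it.service_min,
            },
        })
        for k, pid in enumerate(it.visit_order):
            x, y = net.coords(snap[pid])
            feats.append({
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [x, y]},
                "properties": {
                    "kind": "stop", "day": it.unit_index, "order": k + 1,
                    "target_id": pid, "arrival_min": it.arrivals_min[k],
                },
            })
    fc = {"type": "FeatureCollection",
          "crs_note": "local planar frame, units km",
          "features": feats}
    Path(out).write_text(json.dumps(fc, sort_keys=True, indent=1) + "\n")


def write_matrix_csv(matrix: TravelTimeMatrix, out_path) -> Path:
    """Travel-time matrix as CSV with point ids as header row/column."""
    out = Path(out_path)
    out.parent.mkdir(parents=True, exist_ok=True)
    with open(out, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["point_id"] + [str(p) for p in matrix.point_ids])
        for i, pid in enumerate(matrix.point_ids):
            w.writerow([str(pid)] + [f"{v:.6f}" for v in matrix.minutes[i]])
    return out
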