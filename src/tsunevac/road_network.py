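"""Routable road graph built from road polylines.

Replaces the interactive GIS routing step: polylines (typically exported
from OpenStreetMap) become an undirected graph whose nodes are snapped
polyline endpoints and whose edge weights are Euclidean arc lengths in
metres.  Off-network sites are routed from their nearest node; the
site-to-node offset is reported as a diagnostic, never added to the route
distance, so distances keep the semantics of pure route length.

Shortest paths are Dijkstra's algorithm (via networkx for the distance
field) with a deterministic tie-break: among all minimum-length paths the
lexicographically smallest node sequence is returned.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Hashable, Iterable, Sequence

import networkx as nx

from .geodata_io import FormatError

__all__ = [
    "RoadGraph",
    "Route",
    "build_graph",
    "snap_site",
    "shortest_path",
    "shortest_path_lengths",
    "read_roads_geojson",
    "write_roads_geojson",
    "write_routes_geojson",
]

Point = tuple[float, float]
NodeId = Hashable


def _arc_length(points: Sequence[Point]) -> float:
    return sum(math.dist(a, b) for a, b in zip(points[:-1], points[1:]))


@dataclass(frozen=True)
class Route:
    """A path through the road graph: node sequence, length, geometry."""

    nodes: tuple[NodeId, ...]
    length_m: float
    geometry: tuple[Point, ...]


@dataclass
class RoadGraph:
    """Undirected road graph with planar node coordinates.

    ``graph`` is a :class:`networkx.Graph`; every node has a ``pos``
    attribute (planar metres) and every edge ``length`` (metres) and
    ``geometry`` (the polyline it came from, oriented from the edge's
    u-endpoint).  Self-loops are dropped at construction; between parallel
    polylines only the shortest survives.
    """

    graph: nx.Graph = field(default_factory=nx.Graph)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def position(self, node: NodeId) -> Point:
        return self.graph.nodes[node]["pos"]

    def add_node(self, node: NodeId, pos: Point) -> None:
        self.graph.add_node(node, pos=(float(pos[0]), float(pos[1])))

    def add_edge(
        self, u: NodeId, v: NodeId, geometry: Sequence[Point] | None = None
    ) -> None:
        """Add an edge weighted by the Euclidean arc length of its geometry.

        With no geometry, the straight segment between the endpoints is
        used.  Zero-length and self-loop edges are rejected with a warning
        (the graph stays valid); a parallel edge replaces the stored one
        only if shorter.
        """
        if geometry is None:
            geometry = [self.position(u), self.position(v)]
        geometry = tuple((float(x), float(y)) for x, y in geometry)
        length = _arc_length(geometry)
        if length <= 0.0:
            warnings.warn(f"ignoring zero-length road segment at {geometry[0]}")
            return
        if u == v:
            warnings.warn(f"ignoring self-loop road segment at node {u!r}")
            return
        if self.graph.has_edge(u, v) and self.graph.edges[u, v]["length"] <= length:
            return
        self.graph.add_edge(u, v, length=length, geometry=geometry)


def build_graph(
    polylines: Iterable[Sequence[Point]], snap_tolerance: float = 1.0
) -> RoadGraph:
    """Build a road graph from polylines, merging nearby endpoints.

    Endpoints within ``snap_tolerance`` metres of an existing node are
    merged into it (nearest node wins); each polyline becomes one edge
    weighted by its arc length.  Node ids are consecutive integers in
    discovery order.  Degenerate polylines (fewer than 2 points, or zero
    arc length) are skipped with a warning.
    """
    if snap_tolerance < 0:
        raise ValueError("snap_tolerance must be >= 0")
    rg = RoadGraph()
    nodes: list[tuple[Point, int]] = []  # (position, id); linear scan is fine here

    def node_for(p: Point) -> int:
        best = None
        best_d = math.inf
        for pos, nid in nodes:
            d = math.dist(pos, p)
            if d < best_d:
                best, best_d = nid, d
        if best is not None and best_d <= snap_tolerance:
            return best
        nid = len(nodes)
        rg.add_node(nid, p)
        nodes.append(((float(p[0]), float(p[1])), nid))
        return nid

    for line in polylines:
        if len(line) < 2:
            warnings.warn("ignoring polyline with fewer than 2 points")
            continue
        u = node_for(tuple(line[0]))
        v = node_for(tuple(line[-1]))
        rg.add_edge(u, v, geometry=line)
    return rg


def snap_site(graph: RoadGraph, point: Point) -> NodeId:
    """Nearest graph node to ``point`` (Euclidean); ties -> lowest node id."""
    if graph.n_nodes == 0:
        raise ValueError("cannot snap to an empty road graph")
    return min(
        graph.graph.nodes,
        key=lambda n: (math.dist(graph.position(n), point), _sort_key(n)),
    )


def snap_offset(graph: RoadGraph, point: Point) -> float:
    """Distance from ``point`` to its snapped node (diagnostic only)."""
    return math.dist(graph.position(snap_site(graph, point)), point)


def _sort_key(node: NodeId):
    # mixed int/str node ids must still order deterministically
    return (str(type(node).__name__), node)


def shortest_path(graph: RoadGraph, source: NodeId, target: NodeId) -> Route | None:
    """Minimum-length route between two nodes, or ``None`` if unreachable.

    Among equal-length shortest paths the lexicographically smallest node
    sequence is returned: after computing distances-to-target, the path is
    grown from the source always taking the smallest-id neighbour that
    stays on some shortest path.
    """
    g = graph.graph
    for node in (source, target):
        if node not in g:
            raise KeyError(f"node {node!r} not in road graph")
    if source == target:
        return Route((source,), 0.0, (graph.position(source),))
    dist_to_target = nx.single_source_dijkstra_path_length(g, target, weight="length")
    if source not in dist_to_target:
        return None

    def on_shortest_path(u: NodeId, v: NodeId) -> bool:
        dv = dist_to_target.get(v)
        if dv is None:
            return False
        return math.isclose(
            g.edges[u, v]["length"] + dv, dist_to_target[u], rel_tol=1e-12, abs_tol=1e-9
        )

    nodes = [source]
    geometry: list[Point] = [graph.position(source)]
    current = source
    while current != target:
        nxt = min(
            (v for v in g.neighbors(current) if on_shortest_path(current, v)),
            key=_sort_key,
        )
        geom = g.edges[current, nxt]["geometry"]
        if math.dist(geom[0], graph.position(current)) > math.dist(
            geom[-1], graph.position(current)
        ):
            geom = geom[::-1]
        geometry.extend(geom[1:])
        nodes.append(nxt)
        current = nxt
    return Route(tuple(nodes), dist_to_target[source], tuple(geometry))


def shortest_path_lengths(graph: RoadGraph, source: NodeId) -> dict[NodeId, float]:
    """Network distance from ``source`` to every reachable node."""
    if source not in graph.graph:
        raise KeyError(f"node {source!r} not in road graph")
    return nx.single_source_dijkstra_path_length(graph.graph, source, weight="length")


# ---------------------------------------------------------------------------
# GeoJSON I/O


def _check_planar_crs(obj: dict, path: Path) -> None:
    """Reject GeoJSON that declares a geographic CRS; metres are required."""
    crs = obj.get("crs")
    if crs is None:
        return
    name = str(crs.get("properties", {}).get("name", ""))
    if any(tag in name.upper() for tag in ("4326", "CRS84")):
        raise FormatError(
            f"{path}: geographic coordinates (lon/lat, {name}) are not supported; "
            "project the data to a planar metric CRS first"
        )


def read_roads_geojson(path: str | Path) -> list[list[Point]]:
    """Read road polylines from a GeoJSON FeatureCollection.

    LineString features yield one polyline each; MultiLineString features
    one per part.  Coordinates must be planar metres.
    """
    path = Path(path)
    obj = json.loads(path.read_text("utf-8"))
    _check_planar_crs(obj, path)
    lines: list[list[Point]] = []
    for feature in obj.get("features", []):
        geom = feature.get("geometry") or {}
        gtype = geom.get("type")
        if gtype == "LineString":
            parts = [geom["coordinates"]]
        elif gtype == "MultiLineString":
            parts = geom["coordinates"]
        else:
            continue
        for part in parts:
            lines.append([(float(x), float(y)) for x, y in part])
    return lines


def write_roads_geojson(path: str | Path, polylines: Iterable[Sequence[Point]]) -> None:
    features = [
        {
            "type": "Feature",
            "properties": {},
            "geometry": {
                "type": "LineString",
                "coordinates": [[float(x), float(y)] for x, y in line],
            },
        }
        for line in polylines
    ]
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features}, sort_keys=True),
        "utf-8",
    )


def write_routes_geojson(path: str | Path, routes: Iterable[tuple[str, Route]]) -> None:
    """Write labelled routes as LineStrings with a ``length_m`` property."""
    features = []
    for label, route in routes:
        coords = [[float(x), float(y)] for x, y in route.geometry]
        if len(coords) == 1:  # degenerate single-node route
            coords = [coords[0], coords[0]]
        features.append(
            {
                "type": "Feature",
                "properties": {"name": label, "length_m": route.length_m},
                "geometry": {"type": "LineString", "coordinates": coords},
            }
        )
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features}, sort_keys=True),
        "utf-8",
    )
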