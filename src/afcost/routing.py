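"""Fastest-route computation on the synthetic road network.

Routes minimise travel time, where the speed on each edge is the smaller of
the edge speed limit and the travel-mode cap (walking 4 km/h, bus 30 km/h,
motorised modes bound only by the limit).  All distances are kilometres and
times hours.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import partial
from typing import Hashable, Iterable

import networkx as nx

NodeId = Hashable

MODES = ("car", "taxi", "ambulance", "bus", "walking")

#: flat speed caps (km/h); None means "edge speed limit applies"
MODE_SPEED_CAP: dict[str, float | None] = {
    "car": None,
    "taxi": None,
    "ambulance": None,
    "bus": 30.0,
    "walking": 4.0,
}

FACILITY_KINDS = ("lab", "health_centre", "hospital")


class UnreachableError(RuntimeError):
    """No path exists between the requested origin and destination."""


@dataclass(frozen=True)
class Facility:
    id: str
    kind: str  # lab | health_centre | hospital
    node: NodeId
    bus_accessible: bool = True


@dataclass(frozen=True)
class RouteResult:
    """A time-optimal path with its length and duration (one way)."""

    distance_km: float
    time_h: float
    path: tuple[NodeId, ...]


@dataclass
class Geography:
    """Road network plus facility and bus-stop placements.

    ``graph`` is an undirected :class:`networkx.Graph`; every edge carries
    ``length_km`` (> 0) and ``speed_limit`` (km/h, > 0); every node carries
    a planar position ``pos`` in km.
    """

    graph: nx.Graph
    facilities: dict[str, Facility]
    bus_stops: tuple[NodeId, ...]

    def facilities_of_kind(self, kind: str) -> list[Facility]:
        return sorted(
            (f for f in self.facilities.values() if f.kind == kind), key=lambda f: f.id
        )

    @property
    def labs(self) -> list[Facility]:
        return self.facilities_of_kind("lab")

    @property
    def hospital(self) -> Facility:
        hospitals = self.facilities_of_kind("hospital")
        if len(hospitals) != 1:
            raise ValueError(f"expected exactly one hospital, found {len(hospitals)}")
        return hospitals[0]

    def validate(self) -> None:
        if not nx.is_connected(self.graph):
            raise ValueError("road network must be connected")
        for u, v, data in self.graph.edges(data=True):
            if data["length_km"] <= 0:
                raise ValueError(f"edge ({u}, {v}) has non-positive length")
            if data["speed_limit"] <= 0:
                raise ValueError(f"edge ({u}, {v}) has non-positive speed limit")
        _ = self.hospital
        for f in self.facilities.values():
            if f.kind not in FACILITY_KINDS:
                raise ValueError(f"facility {f.id}: unknown kind {f.kind!r}")
            if f.node not in self.graph:
                raise ValueError(f"facility {f.id}: node {f.node!r} not in network")


def edge_time_h(data: dict, mode: str) -> float:
    cap = MODE_SPEED_CAP[mode]
    speed = data["speed_limit"] if cap is None else min(data["speed_limit"], cap)
    return data["length_km"] / speed


def _time_weight(mode: str):
    return partial(_edge_weight, mode)


def _edge_weight(mode: str, u, v, data) -> float:
    return edge_time_h(data, mode)


def _path_stats(graph: nx.Graph, path: list[NodeId], mode: str) -> tuple[float, float]:
    dist = time = 0.0
    for u, v in zip(path, path[1:]):
        data = graph.edges[u, v]
        dist += data["length_km"]
        time += edge_time_h(data, mode)
    return dist, time


def fastest_route(geo: Geography, origin: NodeId, destination: NodeId, mode: str) -> RouteResult:
    """Time-optimal route between two network nodes for a travel mode.

    Raises :class:`UnreachableError` when no path exists and ``ValueError``
    for unknown nodes or modes.  Parking/service time penalties are *not*
    included here; the cost engine adds them per leg.
    """
    if mode not in MODE_SPEED_CAP:
        raise ValueError(f"unknown travel mode {mode!r}")
    for node in (origin, destination):
        if node not in geo.graph:
            raise ValueError(f"node {node!r} not in network")
    if origin == destination:
        return RouteResult(0.0, 0.0, (origin,))
    try:
        path = nx.dijkstra_path(geo.graph, origin, destination, weight=_time_weight(mode))
    except nx.NetworkXNoPath as exc:
        raise UnreachableError(f"no route from {origin!r} to {destination!r}") from exc
    dist, time = _path_stats(geo.graph, path, mode)
    return RouteResult(dist, time, tuple(path))


def closest_laboratory(geo: Geography, home_node: NodeId) -> tuple[Facility, RouteResult]:
    """Laboratory minimising car-profile travel time from home.

    Ties are broken by facility id; unreachable labs are skipped.
    """
    labs = geo.labs
    if not labs:
        raise ValueError("geography contains no laboratories")
    times = nx.single_source_dijkstra_path_length(geo.graph, home_node, weight=_time_weight("car"))
    best: tuple[float, str, Facility] | None = None
    for lab in labs:
        t = times.get(lab.node)
        if t is None:
            continue
        key = (t, lab.id)
        if best is None or key < (best[0], best[1]):
            best = (t, lab.id, lab)
    if best is None:
        raise UnreachableError(f"no laboratory reachable from {home_node!r}")
    lab = best[2]
    return lab, fastest_route(geo, home_node, lab.node, "car")


def bus_access_distance(geo: Geography, home_node: NodeId) -> float:
    """Network distance (km) from home to the nearest bus stop; inf if none."""
    if not geo.bus_stops:
        return math.inf
    if home_node in set(geo.bus_stops):
        return 0.0
    dists = nx.single_source_dijkstra_path_length(geo.graph, home_node, weight="length_km")
    best = min((dists[s] for s in geo.bus_stops if s in dists), default=math.inf)
    return best


class RoutingIndex:
    """Precomputed shortest-path tables for the pipeline.

    One Dijkstra pass per facility node (car-time profile and pure-length
    profile) plus one multi-source pass for bus stops, so per-journey
    resolution is a dictionary lookup.
    """

    def __init__(self, geo: Geography):
        self.geo = geo
        graph = geo.graph
        self._car_time: dict[NodeId, dict[NodeId, float]] = {}
        self._car_dist: dict[NodeId, dict[NodeId, float]] = {}
        self._length: dict[NodeId, dict[NodeId, float]] = {}
        for node in sorted({f.node for f in geo.facilities.values()}, key=str):
            times, paths = nx.single_source_dijkstra(graph, node, weight=_time_weight("car"))
            self._car_time[node] = times
            self._car_dist[node] = {
                n: _path_stats(graph, p, "car")[0] for n, p in paths.items()
            }
            self._length[node] = nx.single_source_dijkstra_path_length(
                graph, node, weight="length_km"
            )
        if geo.bus_stops:
            self._bus_stop_dist = nx.multi_source_dijkstra_path_length(
                graph, set(geo.bus_stops), weight="length_km"
            )
        else:
            self._bus_stop_dist = {}
        self._nearest_lab: dict[NodeId, Facility] = {}

    def car_route(self, facility_node: NodeId, node: NodeId) -> tuple[float, float]:
        """(distance_km, time_h) of the car fastest route facility <-> node."""
        try:
            return self._car_dist[facility_node][node], self._car_time[facility_node][node]
        except KeyError as exc:
            raise UnreachableError(f"no route between {facility_node!r} and {node!r}") from exc

    def length_distance(self, facility_node: NodeId, node: NodeId) -> float:
        """Shortest network distance (km) facility <-> node."""
        try:
            return self._length[facility_node][node]
        except KeyError as exc:
            raise UnreachableError(f"no route between {facility_node!r} and {node!r}") from exc

    def bus_stop_distance(self, node: NodeId) -> float:
        return self._bus_stop_dist.get(node, math.inf)

    def nearest_lab(self, node: NodeId) -> tuple[Facility, float, float]:
        """(lab, car_distance_km, car_time_h) for the time-closest laboratory."""
        cached = self._nearest_lab.get(node)
        if cached is None:
            best: tuple[float, str, Facility] | None = None
            for lab in self.geo.labs:
                t = self._car_time[lab.node].get(node)
                if t is None:
                    continue
                if best is None or (t, lab.id) < (best[0], best[1]):
                    best = (t, lab.id, lab)
            if best is None:
                raise UnreachableError(f"no laboratory reachable from {node!r}")
            cached = self._nearest_lab[node] = best[2]
        lab = cached
        return lab, self._car_dist[lab.node][node], self._car_time[lab.node][node]

    def nearest_facility(self, node: NodeId, kind: str) -> Facility:
        """Time-closest facility of a kind (ties by id)."""
        best: tuple[float, str, Facility] | None = None
        for fac in self.geo.facilities_of_kind(kind):
            t = self._car_time[fac.node].get(node)
            if t is None:
                continue
            if best is None or (t, fac.id) < (best[0], best[1]):
                best = (t, fac.id, fac)
        if best is None:
            raise UnreachableError(f"no {kind} reachable from {node!r}")
        return best[2]
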