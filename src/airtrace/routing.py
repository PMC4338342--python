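"""Shortest-time routing of trips and space-time trace construction.

Trips are routed over an undirected road network weighted by free-flow link
travel time (length / speed).  Each routed path is discretized at a fixed
arc-length interval (100 m by default) and the per-link times are rescaled so
the discretized trip reproduces the diary's reported travel time exactly.
Dwell episodes contribute single fixed points; the result is a gapless
space-time trace covering the full 1440-minute person-day.
"""

from __future__ import annotations

import heapq
import json
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from . import diary as _diary
from .diary import IN_TRAVEL, PersonDay

__all__ = [
    "RoadNetwork",
    "Path",
    "TracePoint",
    "SpaceTimeTrace",
    "NoRouteError",
    "link_time",
    "shortest_time_path",
    "snap_point",
    "discretize_trip",
    "build_trace",
    "read_network",
    "write_network",
    "trace_to_geojson",
]


class NoRouteError(ValueError):
    """Origin and destination are not connected on the network."""


class RoadNetwork:
    """Undirected planar road network with link lengths and free-flow speeds.

    Backed by a :class:`networkx.Graph`; node attributes ``x``, ``y`` (meters),
    edge attributes ``link_id``, ``length_m``, ``speed_mps``.
    """

    def __init__(self) -> None:
        self.graph = nx.Graph()
        self._node_array_cache: tuple[np.ndarray, np.ndarray] | None = None

    def add_node(self, node_id: int, x: float, y: float) -> None:
        self.graph.add_node(int(node_id), x=float(x), y=float(y))
        self._node_array_cache = None

    def add_link(
        self, link_id: int, u: int, v: int, length_m: float, speed_mps: float
    ) -> None:
        if length_m <= 0 or speed_mps <= 0:
            raise ValueError(
                f"link {link_id}: length and speed must be positive "
                f"(got {length_m}, {speed_mps})"
            )
        if u not in self.graph or v not in self.graph:
            raise ValueError(f"link {link_id}: endpoint not a known node")
        self.graph.add_edge(
            int(u), int(v), link_id=int(link_id), length_m=float(length_m),
            speed_mps=float(speed_mps),
        )

    def node_xy(self, node_id: int) -> tuple[float, float]:
        d = self.graph.nodes[node_id]
        return (d["x"], d["y"])

    @property
    def bbox(self) -> tuple[float, float, float, float]:
        xs = [d["x"] for _, d in self.graph.nodes(data=True)]
        ys = [d["y"] for _, d in self.graph.nodes(data=True)]
        return (min(xs), min(ys), max(xs), max(ys))

    def _node_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        if self._node_array_cache is None:
            ids = np.array(sorted(self.graph.nodes), dtype=int)
            xy = np.array([self.node_xy(int(n)) for n in ids], dtype=float)
            self._node_array_cache = (ids, xy)
        return self._node_array_cache


def link_time(length_m: float, speed_mps: float) -> float:
    """Free-flow traversal time of a link in seconds: length / speed."""
    if speed_mps <= 0:
        raise ValueError(f"speed must be positive, got {speed_mps}")
    if length_m < 0:
        raise ValueError(f"length must be non-negative, got {length_m}")
    return length_m / speed_mps


@dataclass
class Path:
    """A routed path: node sequence plus per-segment geometry and speeds."""

    nodes: list[int]
    coords: list[tuple[float, float]]
    seg_lengths: list[float]
    seg_speeds: list[float]

    @property
    def total_length_m(self) -> float:
        return float(sum(self.seg_lengths))

    @property
    def freeflow_time_s(self) -> float:
        return float(
            sum(L / v for L, v in zip(self.seg_lengths, self.seg_speeds))
        )


def shortest_time_path(
    network: RoadNetwork, origin_node: int, dest_node: int
) -> Path:
    """Minimum free-flow-time path between two nodes.

    Dijkstra with a fully deterministic tie-break: among equal-time paths the
    one with fewer links wins, then the lexicographically smallest node-id
    sequence.  ``origin == destination`` returns an empty zero-time path.
    Disconnected endpoints raise :class:`NoRouteError`.
    """
    g = network.graph
    if origin_node not in g or dest_node not in g:
        raise NoRouteError(f"unknown node {origin_node} or {dest_node}")
    if origin_node == dest_node:
        return Path([origin_node], [network.node_xy(origin_node)], [], [])

    # labels (time, hops, node-sequence) are lexicographically consistent
    # under path extension, so first settlement of a node is optimal
    heap: list[tuple[float, int, tuple[int, ...]]] = [
        (0.0, 0, (origin_node,))
    ]
    settled: set[int] = set()
    while heap:
        t, hops, seq = heapq.heappop(heap)
        node = seq[-1]
        if node in settled:
            continue
        settled.add(node)
        if node == dest_node:
            return _path_from_nodes(network, list(seq))
        for nbr, edata in sorted(g[node].items()):
            if nbr in settled:
                continue
            dt = link_time(edata["length_m"], edata["speed_mps"])
            heapq.heappush(heap, (t + dt, hops + 1, seq + (nbr,)))
    raise NoRouteError(
        f"no route between nodes {origin_node} and {dest_node}"
    )


def _path_from_nodes(network: RoadNetwork, nodes: list[int]) -> Path:
    coords = [network.node_xy(n) for n in nodes]
    lengths, speeds = [], []
    for u, v in zip(nodes[:-1], nodes[1:]):
        e = network.graph.edges[u, v]
        lengths.append(e["length_m"])
        speeds.append(e["speed_mps"])
    return Path(nodes, coords, lengths, speeds)


def snap_point(network: RoadNetwork, point: tuple[float, float]) -> int:
    """Nearest network node to a point (Euclidean); ties go to the smaller id."""
    ids, xy = network._node_arrays()
    if len(ids) == 0:
        raise ValueError("cannot snap onto an empty network")
    d2 = (xy[:, 0] - point[0]) ** 2 + (xy[:, 1] - point[1]) ** 2
    return int(ids[int(np.argmin(d2))])  # ids sorted, argmin returns first min


@dataclass
class TracePoint:
    """One discretized space-time element: a location held for ``dt`` minutes."""

    x: float
    y: float
    t_start: float  # minute of day
    dt: float  # minutes, > 0
    kind: str


@dataclass
class SpaceTimeTrace:
    """Full-day sequence of trace points for one person-day."""

    person_id: str
    residence: tuple[float, float]
    points: list[TracePoint] = field(default_factory=list)

    @property
    def total_minutes(self) -> float:
        return float(sum(p.dt for p in self.points))


def _position_at(path: Path, s: float) -> tuple[float, float]:
    """Point at arc length ``s`` along the path polyline."""
    remaining = s
    for (x0, y0), (x1, y1), L in zip(
        path.coords[:-1], path.coords[1:], path.seg_lengths
    ):
        if remaining <= L or L == 0:
            f = 0.0 if L == 0 else remaining / L
            return (x0 + f * (x1 - x0), y0 + f * (y1 - y0))
        remaining -= L
    return path.coords[-1]


def _cumulative_scaled_time(path: Path, s: float, ratio: float) -> float:
    """Scaled travel time (seconds) to reach arc length ``s``.

    Each link's free-flow time is multiplied by ``ratio``; within a link the
    traversal is uniform, so time accumulates piecewise linearly in s.
    """
    t = 0.0
    remaining = s
    for L, v in zip(path.seg_lengths, path.seg_speeds):
        if remaining <= L:
            return t + ratio * remaining / v
        t += ratio * L / v
        remaining -= L
    return t


def discretize_trip(
    path: Path, reported_travel_minutes: float, interval_m: float = 100.0
) -> list[TracePoint]:
    """Sample a path every ``interval_m`` of arc length, with exact trip time.

    Sample positions sit at arc lengths 0, interval, 2·interval, … plus the
    terminal endpoint (duplicates suppressed).  Link free-flow times are
    rescaled by ``reported / free-flow`` so each sample's dt is the scaled
    traversal time of the arc span reaching from the midpoint toward the
    previous sample to the midpoint toward the next (end samples extend to the
    path ends).  The last dt absorbs float residue so the dt's sum to the
    reported travel time exactly.  ``t_start`` values are trip-relative
    (first sample at 0); callers offset them to the time of day.
    """
    if reported_travel_minutes <= 0:
        raise ValueError("reported travel time must be positive")
    total = path.total_length_m
    if total == 0:
        x, y = path.coords[0]
        return [TracePoint(x, y, 0.0, reported_travel_minutes, IN_TRAVEL)]
    ratio = (reported_travel_minutes * 60.0) / path.freeflow_time_s

    stations = [float(k) * interval_m for k in range(int(total // interval_m) + 1)]
    if total - stations[-1] > 1e-9:
        stations.append(total)
    elif len(stations) > 1:
        stations[-1] = total  # terminal sample, duplicate suppressed

    # span boundaries: path start, inter-sample midpoints, path end
    bounds = [0.0]
    bounds += [(a + b) / 2.0 for a, b in zip(stations[:-1], stations[1:])]
    bounds.append(total)

    points: list[TracePoint] = []
    t_cursor = 0.0
    for k, s in enumerate(stations):
        x, y = _position_at(path, s)
        t_hi = _cumulative_scaled_time(path, bounds[k + 1], ratio) / 60.0
        dt = t_hi - t_cursor
        points.append(TracePoint(x, y, t_cursor, dt, IN_TRAVEL))
        t_cursor = t_hi
    # exact conservation: last span absorbs rounding
    points[-1].dt += reported_travel_minutes - t_cursor
    return points


def _clip_travel_points(
    points: list[TracePoint], window: tuple[float, float]
) -> list[TracePoint]:
    """Keep the [w0, w1) sub-interval of trip-relative travel time."""
    w0, w1 = window
    out = []
    for p in points:
        lo = max(p.t_start, w0)
        hi = min(p.t_start + p.dt, w1)
        if hi - lo > 0:
            out.append(TracePoint(p.x, p.y, lo - w0, hi - lo, IN_TRAVEL))
    return out


def build_trace(
    person_day: PersonDay,
    network: RoadNetwork,
    interval_m: float = 100.0,
    _path_cache: dict | None = None,
) -> SpaceTimeTrace:
    """Assemble the full-day space-time trace of a filtered, pared record.

    Dwell episodes become single fixed trace points; travel episodes expand
    into discretized routed points (trip endpoints snapped to the nearest
    network node).  Routing failures are re-raised annotated with the trip
    index.  Total trace time is exactly 1440 minutes.
    """
    episodes = _diary.build_timeline(person_day)
    trace = SpaceTimeTrace(person_day.person_id, person_day.residence)
    for ep in episodes:
        if ep.kind != IN_TRAVEL or ep.trip_index is None:
            trace.points.append(
                TracePoint(ep.location[0], ep.location[1], ep.start_minute,
                           ep.duration_minutes, ep.kind)
            )
            continue
        trip = person_day.trips[ep.trip_index]
        o = snap_point(network, trip.origin)
        d = snap_point(network, trip.destination)
        key = (o, d)
        try:
            if _path_cache is not None and key in _path_cache:
                path = _path_cache[key]
            else:
                path = shortest_time_path(network, o, d)
                if _path_cache is not None:
                    _path_cache[key] = path
            pts = discretize_trip(path, trip.reported_travel_minutes, interval_m)
        except (NoRouteError, ValueError) as exc:
            raise NoRouteError(
                f"person-day {person_day.person_id}, trip {ep.trip_index}: {exc}"
            ) from exc
        if trip.travel_window is not None:
            pts = _clip_travel_points(pts, trip.travel_window)
        for p in pts:
            p.t_start += ep.start_minute
            trace.points.append(p)
    # exact day closure (mirrors the timeline's residue absorption)
    total = 0.0
    for p in trace.points:
        total += p.dt
    trace.points[-1].dt += _diary.DAY_MINUTES - total
    return trace


# ---------------------------------------------------------------------------
# I/O: GMNS-like node/link CSV pair; optional GeoJSON trace export
# ---------------------------------------------------------------------------

def write_network(network: RoadNetwork, nodes_path, links_path) -> None:
    nodes = pd.DataFrame(
        [
            {"id": n, "x": d["x"], "y": d["y"]}
            for n, d in sorted(network.graph.nodes(data=True))
        ]
    )
    links = pd.DataFrame(
        [
            {
                "id": d["link_id"],
                "from": min(u, v),
                "to": max(u, v),
                "length_m": d["length_m"],
                "speed_mps": d["speed_mps"],
            }
            for u, v, d in network.graph.edges(data=True)
        ]
    ).sort_values("id")
    nodes.to_csv(nodes_path, index=False, lineterminator="\n")
    links.to_csv(links_path, index=False, lineterminator="\n")


def read_network(nodes_path, links_path) -> RoadNetwork:
    nodes = pd.read_csv(nodes_path)
    links = pd.read_csv(links_path)
    net = RoadNetwork()
    for row in nodes.itertuples(index=False):
        net.add_node(int(row.id), float(row.x), float(row.y))
    for lid, u, v, length, speed in links[
        ["id", "from", "to", "length_m", "speed_mps"]
    ].itertuples(index=False, name=None):
        net.add_link(int(lid), int(u), int(v), float(length), float(speed))
    return net


def trace_to_geojson(trace: SpaceTimeTrace) -> str:
    """Serialize a trace as a GeoJSON MultiPoint feature with time properties."""
    feature = {
        "type": "Feature",
        "geometry": {
            "type": "MultiPoint",
            "coordinates": [[p.x, p.y] for p in trace.points],
        },
        "properties": {
            "person_id": trace.person_id,
            "t_start": [p.t_start for p in trace.points],
            "dt": [p.dt for p in trace.points],
            "kind": [p.kind for p in trace.points],
        },
    }
    return json.dumps(feature, sort_keys=True)
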