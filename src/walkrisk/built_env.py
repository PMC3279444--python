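"""Walkability variables and neighborhood classification.

Three household-level built-environment variables are computed:

* population density — people/km2 of the census tract containing the home;
* intersection density — number of street-network nodes with three or more
  non-freeway road segments within a 1-km network (shortest-path) buffer
  of the home;
* land-use mix — normalized entropy of the area shares of the four primary
  land uses (residential, commercial, retail, institutional) within the
  buffer footprint, ranging 0 (single use) to 1 (equal four-way mixture).

Households in the upper tertile of all three variables are classified
high-walkability; lower tertile of all three, low-walkability; everything
else is middle.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import shapely
from shapely.geometry import LineString, MultiPoint, Point, Polygon
from shapely.ops import unary_union

from .config import WalkabilitySettings
from .synthetic_city import PRIMARY_LAND_USES, Parcel, Tract

logger = logging.getLogger(__name__)


def population_density(participants: pd.DataFrame, tracts: list[Tract]) -> pd.Series:
    """Tract population / tract area (people/km2) for each home location."""
    tracts = sorted(tracts, key=lambda t: t.tract_id)
    tree = shapely.STRtree([t.polygon for t in tracts])
    pts = shapely.points(participants.home_x.to_numpy(float), participants.home_y.to_numpy(float))
    dens = np.full(len(participants), np.nan)
    pt_idx, tr_idx = tree.query(pts, predicate="intersects")
    # first (lowest tract_id) match wins if a home sits on a shared boundary
    for p_i, t_i in zip(pt_idx, tr_idx):
        if np.isnan(dens[p_i]):
            t = tracts[t_i]
            dens[p_i] = t.population / (t.polygon.area / 1e6)
    missing = np.isnan(dens)
    if missing.any():
        bad = participants.participant_id.to_numpy()[missing][:5]
        raise ValueError(f"home outside all tracts for participant(s): {list(bad)}")
    return pd.Series(dens, index=participants.index, name="population_density")


@dataclass
class NetworkBuffer:
    """All street-network nodes within a shortest-path radius of a home
    snapped onto the (non-freeway) road network."""

    snapped_point: tuple[float, float]
    edge: tuple | None  # (u, v) of the snapped edge, None if empty
    radius: float
    node_distances: dict = field(default_factory=dict)  # node -> network distance

    @property
    def empty(self) -> bool:
        return self.edge is None

    @property
    def nodes(self) -> list:
        return list(self.node_distances)

    def points(self, graph: nx.Graph) -> np.ndarray:
        coords = [self.snapped_point] + [
            (graph.nodes[n]["x"], graph.nodes[n]["y"]) for n in self.node_distances
        ]
        return np.asarray(coords)


class RoadIndex:
    """Spatial + shortest-path index over a road graph; caches truncated
    Dijkstra trees so cohorts of nearby homes stay cheap."""

    def __init__(self, graph: nx.Graph, exclude_freeways: bool = True):
        self.full = graph
        if exclude_freeways:
            g = graph.edge_subgraph(
                [(u, v) for u, v, d in graph.edges(data=True) if not d.get("freeway", False)]
            ).copy()
        else:
            g = graph
        self.graph = g
        self._edges = list(g.edges)
        self._lines = [
            LineString(
                [
                    (g.nodes[u]["x"], g.nodes[u]["y"]),
                    (g.nodes[v]["x"], g.nodes[v]["y"]),
                ]
            )
            for u, v in self._edges
        ]
        self._tree = shapely.STRtree(self._lines) if self._lines else None
        self._dijkstra_cache: dict = {}
        self._degree = dict(g.degree)

    def snap(self, x: float, y: float):
        """Nearest point on the nearest edge: returns (edge, snapped_xy,
        offset_from_u, snap_distance)."""
        if self._tree is None:
            return None
        idx = int(self._tree.query_nearest(Point(x, y))[0])
        line = self._lines[idx]
        off = line.project(Point(x, y))
        sp = line.interpolate(off)
        return self._edges[idx], (sp.x, sp.y), float(off), float(Point(x, y).distance(sp))

    def dijkstra(self, node, cutoff: float) -> dict:
        key = (node, cutoff)
        if key not in self._dijkstra_cache:
            self._dijkstra_cache[key] = nx.single_source_dijkstra_path_length(
                self.graph, node, cutoff=cutoff, weight="length"
            )
        return self._dijkstra_cache[key]

    def degree(self, node) -> int:
        return self._degree.get(node, 0)


def network_buffer(
    home: tuple[float, float],
    roads: nx.Graph | RoadIndex,
    radius: float = 1000.0,
    exclude_freeways: bool = True,
    snap_max_distance: float = 500.0,
) -> NetworkBuffer:
    """Shortest-path buffer of ``radius`` meters around a home snapped to
    the nearest non-freeway edge point. Homes with no non-freeway edge
    within ``snap_max_distance`` get an empty buffer and a warning."""
    index = roads if isinstance(roads, RoadIndex) else RoadIndex(roads, exclude_freeways)
    snapped = index.snap(*home)
    if snapped is None or snapped[3] > snap_max_distance:
        warnings.warn(
            f"no non-freeway edge within {snap_max_distance:.0f} m of home {home}; empty buffer",
            stacklevel=2,
        )
        return NetworkBuffer(snapped_point=tuple(home), edge=None, radius=radius)
    (u, v), sp, off, _ = snapped
    edge_len = index.graph.edges[u, v]["length"]
    dist: dict = {}
    for anchor, anchor_off in ((u, off), (v, edge_len - off)):
        if anchor_off > radius:
            continue
        for node, d in index.dijkstra(anchor, radius).items():
            total = anchor_off + d
            if total <= radius and total < dist.get(node, np.inf):
                dist[node] = total
    return NetworkBuffer(snapped_point=sp, edge=(u, v), radius=radius, node_distances=dist)


def intersection_density(buffer: NetworkBuffer, roads: nx.Graph | RoadIndex) -> int:
    """Count of true intersections (>= 3 non-freeway segments meeting)
    inside the network buffer."""
    if buffer.empty:
        return 0
    index = roads if isinstance(roads, RoadIndex) else RoadIndex(roads)
    return int(sum(1 for n in buffer.node_distances if index.degree(n) >= 3))


def land_use_mix(areas) -> float:
    """Normalized entropy of four primary land-use area shares, in [0, 1].

    ``areas`` maps class -> area (or is a length-4 sequence). 1 means an
    equal four-way mixture, 0 a single use (or no primary-use area at all).
    """
    if isinstance(areas, dict):
        a = np.array([float(areas.get(c, 0.0)) for c in PRIMARY_LAND_USES])
    else:
        a = np.asarray(areas, dtype=float)
    if (a < 0).any():
        raise ValueError("negative parcel area")
    total = a.sum()
    if total == 0:
        return 0.0
    p = a[a > 0] / total
    return float(-(p * np.log(p)).sum() / np.log(len(PRIMARY_LAND_USES)) + 0.0)


def buffer_footprint(
    buffer: NetworkBuffer,
    roads: nx.Graph | RoadIndex,
    mode: str = "convex_hull",
    corridor_half_width: float = 50.0,
) -> Polygon:
    """Convert a network buffer into an areal footprint, either the convex
    hull of the reached network points or a union of corridors around the
    reached edges."""
    graph = roads.graph if isinstance(roads, RoadIndex) else roads
    if buffer.empty:
        return Point(buffer.snapped_point).buffer(1.0)
    if mode == "convex_hull":
        hull = MultiPoint([tuple(p) for p in buffer.points(graph)]).convex_hull
        if hull.area == 0:  # degenerate: point or collinear nodes
            hull = hull.buffer(corridor_half_width)
        return hull
    if mode == "corridor":
        nodes = buffer.node_distances
        lines = [
            LineString(
                [
                    (graph.nodes[u]["x"], graph.nodes[u]["y"]),
                    (graph.nodes[v]["x"], graph.nodes[v]["y"]),
                ]
            )
            for u, v in graph.edges
            if u in nodes and v in nodes
        ]
        lines.append(LineString([buffer.snapped_point,
                                 (graph.nodes[buffer.edge[0]]["x"], graph.nodes[buffer.edge[0]]["y"])]))
        return unary_union(lines).buffer(corridor_half_width)
    raise ValueError(f"unknown footprint mode {mode!r}")


def land_use_areas(footprint: Polygon, parcels: list[Parcel], tree: shapely.STRtree | None = None) -> dict[str, float]:
    """Area of each primary land-use class inside the footprint (m2)."""
    if tree is None:
        tree = shapely.STRtree([p.polygon for p in parcels])
    areas = {c: 0.0 for c in PRIMARY_LAND_USES}
    for idx in tree.query(footprint, predicate="intersects"):
        parcel = parcels[int(idx)]
        if parcel.land_use in areas:
            areas[parcel.land_use] += footprint.intersection(parcel.polygon).area
    return areas


def tertile_indices(values: pd.Series, bins: str = "tertiles") -> tuple[pd.Series, np.ndarray]:
    """Bin a variable into cohort tertiles (or deciles). Values equal to a
    cut point go to the lower bin; cuts use linear-interpolation quantiles."""
    v = values.to_numpy(float)
    if np.min(v) == np.max(v):
        raise ValueError(
            f"variable {values.name!r} is constant; tertiles undefined — inspect the input"
        )
    n_bins = {"tertiles": 3, "deciles": 10}[bins]
    cuts = np.percentile(v, np.linspace(0, 100, n_bins + 1)[1:-1])
    idx = np.searchsorted(cuts, v, side="left")  # value == cut -> lower bin
    return pd.Series(idx, index=values.index), cuts


def classify_walkability(be_table: pd.DataFrame, bins: str = "tertiles") -> pd.DataFrame:
    """Assign high/low/middle walkability from the joint upper/lower bin
    rule over the three built-environment variables."""
    if len(be_table) < 3:
        raise ValueError("need at least 3 participants to classify walkability")
    variables = ["population_density", "intersection_density", "land_use_mix"]
    n_bins = {"tertiles": 3, "deciles": 10}[bins]
    out = be_table[["participant_id"] + variables].copy()
    for var in variables:
        out[f"{var}_bin"], _ = tertile_indices(be_table[var], bins)
    bin_cols = [f"{v}_bin" for v in variables]
    top = (out[bin_cols] == n_bins - 1).all(axis=1)
    bottom = (out[bin_cols] == 0).all(axis=1)
    out["walkability_class"] = np.select([top, bottom], ["high", "low"], default="middle")
    logger.info(
        "walkability classes (%s, ties to lower bin): %s",
        bins,
        out.walkability_class.value_counts().to_dict(),
    )
    return out


class BuiltEnvironment:
    """Compute the three walkability variables for a cohort.

    Buffers and land-use areas depend only on the snapped network location,
    so results are cached on (edge, quantized offset) — households on the
    same block share the computation.
    """

    def __init__(
        self,
        roads: nx.Graph,
        tracts: list[Tract],
        parcels: list[Parcel],
        settings: WalkabilitySettings | None = None,
    ):
        self.settings = settings or WalkabilitySettings()
        self.index = RoadIndex(roads, self.settings.exclude_freeways)
        self.tracts = tracts
        self.parcels = parcels
        self._parcel_tree = shapely.STRtree([p.polygon for p in parcels]) if parcels else None
        self._cache: dict = {}

    def _at_location(self, x: float, y: float) -> tuple[int, float, bool]:
        snapped = self.index.snap(x, y)
        if snapped is None or snapped[3] > self.settings.snap_max_distance_m:
            return 0, 0.0, True
        edge, _, off, _ = snapped
        key = (edge, round(off / 25.0))
        if key not in self._cache:
            buf = network_buffer(
                (x, y),
                self.index,
                radius=self.settings.buffer_radius_m,
                snap_max_distance=self.settings.snap_max_distance_m,
            )
            n_int = intersection_density(buf, self.index)
            fp = buffer_footprint(
                buf, self.index, self.settings.footprint, self.settings.corridor_half_width_m
            )
            areas = land_use_areas(fp, self.parcels, self._parcel_tree)
            self._cache[key] = (n_int, land_use_mix(areas), False)
        return self._cache[key]

    def compute(self, participants: pd.DataFrame) -> pd.DataFrame:
        dens = population_density(participants, self.tracts)
        rows = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # per-home snap warnings roll up into the flag
            for x, y in zip(participants.home_x.to_numpy(float), participants.home_y.to_numpy(float)):
                rows.append(self._at_location(x, y))
        out = pd.DataFrame(rows, columns=["intersection_density", "land_use_mix", "flagged"],
                           index=participants.index)
        out.insert(0, "participant_id", participants.participant_id)
        out.insert(1, "population_density", dens)
        n_flagged = int(out.flagged.sum())
        if n_flagged:
            logger.warning("%d household(s) flagged (unsnappable or zero-area buffer)", n_flagged)
        return out
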