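"""Candidate migration-trail search on the T-cell node graph.

Two complementary searches over the directed node graph G(V, E):

* **Minimum-spanning path** — edges connect nodes closer than ``d_max``
  (130 um by default, one hex-lattice step plus slack), oriented from lower
  to higher exhaustion score with weight equal to the score difference;
  Dijkstra's algorithm finds the lightest start-to-end path.  Because every
  directed path telescopes to ``z_end - z_start``, the deterministic
  tie-break (fewest hops, then lexicographic node ids) decides among
  routes of equal weight.
* **3D line** — after rescaling x and y onto the exhaustion-score range,
  nodes lying within a small perpendicular distance of the 3D segment from
  start to end are collected and ordered by their projection onto it.  This
  tolerates small score fluctuations along the trail; trails with a large
  score *drawback* between consecutive nodes are rejected.

Trails shorter than ``min_nodes`` or spanning less than ``min_span``
(0.5 mm) between endpoints are excluded by both methods.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

D_MAX_UM = 130.0
MIN_SPAN_UM = 500.0
MIN_NODES = 6
ENDPOINT_FRAC = 0.33


@dataclass(frozen=True)
class Trail:
    """An ordered sequence of adjacent T-cell nodes (1-based indexing)."""

    nodes: tuple
    methods: tuple  # subset of ("dijkstra", "line3d")
    span_um: float
    z_profile: tuple

    def __len__(self) -> int:
        return len(self.nodes)

    @property
    def indices(self) -> tuple:
        return tuple(range(1, len(self.nodes) + 1))

    @property
    def start(self):
        return self.nodes[0]

    @property
    def end(self):
        return self.nodes[-1]


def validate_trail(trail: Trail, nodes: pd.DataFrame,
                   d_max: float = D_MAX_UM, min_nodes: int = MIN_NODES,
                   min_span: float = MIN_SPAN_UM) -> None:
    """Runtime checker for the trail contract (also used by the tests)."""
    if len(trail) < min_nodes:
        raise ValueError(f"trail has {len(trail)} nodes, needs >= {min_nodes}")
    if len(set(trail.nodes)) != len(trail.nodes):
        raise ValueError("trail revisits a node")
    pos = nodes.set_index("node_id")[["x", "y"]]
    xy = pos.loc[list(trail.nodes)].to_numpy(float)
    steps = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    if steps.size and steps.max() >= d_max:
        raise ValueError(f"consecutive nodes {steps.max():.1f} um apart (>= {d_max})")
    span = float(np.linalg.norm(xy[-1] - xy[0]))
    if span < min_span:
        raise ValueError(f"span {span:.1f} um below {min_span}")
    if abs(span - trail.span_um) > 1e-6:
        raise ValueError("recorded span does not match coordinates")


def _span(nodes: pd.DataFrame, a, b) -> float:
    pos = nodes.set_index("node_id")
    dx = pos.at[a, "x"] - pos.at[b, "x"]
    dy = pos.at[a, "y"] - pos.at[b, "y"]
    return float(np.hypot(dx, dy))


def build_graph(nodes: pd.DataFrame, d_max: float = D_MAX_UM) -> nx.DiGraph:
    """Directed weighted adjacency over T-cell nodes.

    Nodes closer than ``d_max`` in 2D are joined by a single edge pointing
    from the lower to the higher exhaustion score, weighted by the score
    difference.  Equal scores are oriented by node id, which keeps the graph
    acyclic.
    """
    if d_max <= 0:
        raise ValueError("d_max must be positive")
    if nodes.empty:
        raise ValueError("empty node table")
    g = nx.DiGraph(d_max=d_max)
    ids = nodes["node_id"].to_numpy()
    xy = nodes[["x", "y"]].to_numpy(float)
    z = nodes["z"].to_numpy(float)
    for i in range(len(ids)):
        g.add_node(ids[i], x=xy[i, 0], y=xy[i, 1], z=z[i])
    tree = cKDTree(xy)
    for i, j in tree.query_pairs(d_max):  # strictly < d_max
        u, v = ids[i], ids[j]
        if z[i] < z[j] or (z[i] == z[j] and str(u) < str(v)):
            g.add_edge(u, v, weight=z[j] - z[i])
        else:
            g.add_edge(v, u, weight=abs(z[j] - z[i]))
    return g


def candidate_endpoints(nodes: pd.DataFrame, frac: float = ENDPOINT_FRAC):
    """Potential trail starts (lowest-score tercile) and ends (highest).

    Returns ``(starts, ends)`` as lists of node ids; ties in score are broken
    by node id.  At least one start and one end are always returned.
    """
    if not 0 < frac <= 0.5:
        raise ValueError("frac must lie in (0, 0.5]")
    n = len(nodes)
    if n < 3:
        raise ValueError("need at least 3 nodes")
    m = max(1, int(np.floor(frac * n)))
    order = sorted(zip(nodes["z"], nodes["node_id"].astype(str), nodes["node_id"]))
    starts = [t[2] for t in order[:m]]
    ends = [t[2] for t in order[-m:]]
    return starts, ends


def _make_trail(g: nx.DiGraph, path, method: str) -> Trail:
    xy = np.array([[g.nodes[n]["x"], g.nodes[n]["y"]] for n in path])
    z = tuple(float(g.nodes[n]["z"]) for n in path)
    span = float(np.linalg.norm(xy[-1] - xy[0]))
    return Trail(nodes=tuple(path), methods=(method,), span_um=span, z_profile=z)


def dijkstra_single_source(g: nx.DiGraph, s) -> dict:
    """Deterministic Dijkstra from ``s`` to every reachable node.

    Paths are compared by (total weight, hop count, node-id sequence), so the
    returned path for each target is unique regardless of insertion order.
    Returns ``{target: (weight, path_tuple)}``.
    """
    best: dict = {}
    heap = [(0.0, 0, (str(s),), (s,))]
    done = set()
    while heap:
        dist, hops, _key, path = heapq.heappop(heap)
        node = path[-1]
        if node in done:
            continue
        done.add(node)
        best[node] = (dist, path)
        for _, nbr, data in g.out_edges(node, data=True):
            if nbr in done:
                continue
            npath = path + (nbr,)
            heapq.heappush(
                heap,
                (dist + data["weight"], hops + 1,
                 tuple(str(n) for n in npath), npath),
            )
    return best


def dijkstra_trail(g: nx.DiGraph, s, e) -> Trail | None:
    """Minimum-total-weight directed path from ``s`` to ``e``, or None."""
    if s not in g or e not in g:
        raise KeyError(f"{s!r} or {e!r} not in graph")
    reach = dijkstra_single_source(g, s)
    if e not in reach:
        return None
    _, path = reach[e]
    return _make_trail(g, path, "dijkstra")


def filter_trails(trails, min_nodes: int = MIN_NODES,
                  min_span: float = MIN_SPAN_UM) -> list:
    """Drop trails that are too short in nodes or in start-end span."""
    return [t for t in trails
            if len(t) >= min_nodes and t.span_um >= min_span]


# ---------------------------------------------------------------------------
# 3D line method
# ---------------------------------------------------------------------------

def rescale_xy_to_z(nodes: pd.DataFrame) -> np.ndarray:
    """Affinely map x and y onto the exhaustion-score range.

    Returns an ``(n, 3)`` array of rescaled (x, y, z) coordinates.  Requires
    a non-degenerate score range.
    """
    z = nodes["z"].to_numpy(float)
    zmin, zmax = z.min(), z.max()
    if zmax <= zmin:
        raise ValueError("exhaustion-score range is zero; 3D rescaling undefined")
    out = np.empty((len(nodes), 3))
    for k, col in enumerate(("x", "y")):
        v = nodes[col].to_numpy(float)
        lo, hi = v.min(), v.max()
        if hi > lo:
            out[:, k] = zmin + (v - lo) * (zmax - zmin) / (hi - lo)
        else:
            out[:, k] = zmin
    out[:, 2] = z
    return out


def point_segment_distance(points: np.ndarray, a: np.ndarray,
                           b: np.ndarray) -> tuple:
    """Distances of 3D ``points`` to segment a-b and their projections.

    Returns ``(distances, t)`` where ``t`` is the unclamped scalar projection
    of each point onto the segment direction (0 at ``a``, 1 at ``b``).
    """
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0:
        return np.linalg.norm(points - a, axis=1), np.zeros(len(points))
    t = (points - a) @ ab / denom
    closest = a + np.clip(t, 0.0, 1.0)[:, None] * ab
    return np.linalg.norm(points - closest, axis=1), t


def line3d_collect(nodes: pd.DataFrame, s, e, dist_cutoff: float,
                   coords3d: np.ndarray | None = None) -> list:
    """Nodes within ``dist_cutoff`` of the 3D segment s->e, projection-ordered.

    The segment is oriented so that ordering starts at the endpoint with the
    smaller exhaustion score.  This is the geometric core of the 3D-line
    method, before any trail-level constraint is applied.
    """
    if dist_cutoff <= 0:
        raise ValueError("dist_cutoff must be positive")
    if coords3d is None:
        coords3d = rescale_xy_to_z(nodes)
    ids = nodes["node_id"].to_numpy()
    lookup = {n: i for i, n in enumerate(ids)}
    si, ei = lookup[s], lookup[e]
    if coords3d[si, 2] > coords3d[ei, 2]:
        si, ei = ei, si
    a, b = coords3d[si], coords3d[ei]
    dist, t = point_segment_distance(coords3d, a, b)
    member = np.flatnonzero(dist <= dist_cutoff)
    order = sorted(member, key=lambda i: (t[i], str(ids[i])))
    return [ids[i] for i in order]


def line3d_trails(nodes: pd.DataFrame, starts, ends,
                  dist_cutoff: float | None = None,
                  d_max: float = D_MAX_UM,
                  drawback_tol: float | None = None,
                  min_nodes: int = MIN_NODES,
                  min_span: float = MIN_SPAN_UM) -> list:
    """All 3D-line trails over admissible (start, end) pairs.

    ``dist_cutoff`` defaults to 5% of the score range (the rescaled
    coordinate scale); ``drawback_tol`` defaults to 10% of each trail's total
    score span.  A candidate is rejected when consecutive nodes are farther
    than ``d_max`` apart in 2D, when it is too short, or when the score drops
    by more than ``drawback_tol`` between consecutive nodes.
    """
    coords3d = rescale_xy_to_z(nodes)
    z = dict(zip(nodes["node_id"], nodes["z"].astype(float)))
    xy = {n: (x, y) for n, x, y in zip(nodes["node_id"], nodes["x"], nodes["y"])}
    if dist_cutoff is None:
        # "small" capture distance: 5% of the score range, but never wider
        # than ~half an adjacency step in rescaled units, so that lateral
        # lattice neighbors of a trail do not fall inside the cylinder
        zr = float(np.ptp(nodes["z"].to_numpy(float)))
        xr = float(np.ptp(nodes["x"].to_numpy(float)))
        yr = float(np.ptp(nodes["y"].to_numpy(float)))
        scale = zr / max(xr, yr) if max(xr, yr) > 0 else 1.0
        dist_cutoff = min(0.05 * zr, 0.6 * d_max * scale)
    if dist_cutoff <= 0:
        raise ValueError("dist_cutoff must be positive")

    trails = []
    for s in starts:
        for e in ends:
            if s == e:
                continue
            sx, sy = xy[s]
            ex, ey = xy[e]
            span = float(np.hypot(ex - sx, ey - sy))
            if span < min_span:
                continue
            seq = line3d_collect(nodes, s, e, dist_cutoff, coords3d=coords3d)
            if len(seq) < min_nodes:
                continue
            pts = np.array([xy[n] for n in seq])
            steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
            if steps.max() >= d_max:
                continue
            zs = np.array([z[n] for n in seq])
            tol = (0.1 * float(zs.max() - zs.min())
                   if drawback_tol is None else drawback_tol)
            drawback = np.diff(zs)
            if drawback.min() < -tol:
                continue
            tspan = float(np.linalg.norm(pts[-1] - pts[0]))
            trails.append(Trail(nodes=tuple(seq), methods=("line3d",),
                                span_um=tspan, z_profile=tuple(map(float, zs))))
    return trails


# ---------------------------------------------------------------------------
# combined candidate generation
# ---------------------------------------------------------------------------

def find_candidate_trails(g: nx.DiGraph, nodes: pd.DataFrame,
                          frac: float = ENDPOINT_FRAC,
                          dist_cutoff: float | None = None,
                          drawback_tol: float | None = None,
                          min_nodes: int = MIN_NODES,
                          min_span: float = MIN_SPAN_UM) -> list:
    """Union of Dijkstra and 3D-line candidates, deduplicated by sequence.

    Start/end pairs closer than ``min_span`` are skipped up front (they could
    never pass the span filter).  A trail found by both methods is reported
    once with both method tags.
    """
    starts, ends = candidate_endpoints(nodes, frac=frac)
    pos = nodes.set_index("node_id")[["x", "y"]]
    d_max = g.graph.get("d_max", D_MAX_UM)

    seen: dict = {}

    def _add(trail: Trail) -> None:
        key = trail.nodes
        if key in seen:
            merged = tuple(sorted(set(seen[key].methods) | set(trail.methods)))
            seen[key] = replace(seen[key], methods=merged)
        else:
            seen[key] = trail

    for s in starts:
        reach = dijkstra_single_source(g, s)
        sx, sy = pos.at[s, "x"], pos.at[s, "y"]
        for e in ends:
            if e == s or e not in reach:
                continue
            span = float(np.hypot(pos.at[e, "x"] - sx, pos.at[e, "y"] - sy))
            if span < min_span:
                continue
            trail = _make_trail(g, reach[e][1], "dijkstra")
            if len(trail) >= min_nodes:
                _add(trail)

    if np.ptp(nodes["z"].to_numpy(float)) > 0:
        for trail in line3d_trails(nodes, starts, ends,
                                   dist_cutoff=dist_cutoff, d_max=d_max,
                                   drawback_tol=drawback_tol,
                                   min_nodes=min_nodes, min_span=min_span):
            _add(trail)

    return sorted(seen.values(), key=lambda t: tuple(map(str, t.nodes)))
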