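"""Vascular structure graph (VSG) construction from a 1-px vessel skeleton.

Nodes are vessel bifurcations (>= 3 skeleton branches) and segment endpoints
(exactly 1 branch); edges are the vessel segments between them, attributed
with the vessel path distance ``d_vp`` (arc length along the skeleton) and
the Euclidean endpoint distance ``d_e``.  Both attributes are normalized by
their per-graph mean — ``a1 = d_vp / mean(d_vp)``, ``a2 = d_e / mean(d_e)`` —
which makes them invariant to uniform scaling of the image, the property the
graph matcher relies on.  Nodes are treated uniformly during matching; the
bifurcation/endpoint kind is metadata only.

Coordinates are (row, col), 0-based, pixel centers at integer positions.
"""

from __future__ import annotations

import dataclasses
import json
import logging

import numpy as np
from scipy import ndimage

from .errors import EmptyGraphError, ParameterError
from .vessels import CenterlineImage

log = logging.getLogger(__name__)

# 8-neighborhood in circular order (for crossing-number computation).
_RING = ((-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1))
# deterministic scan order for tracing
_NBRS = ((-1, 0), (0, -1), (0, 1), (1, 0), (-1, -1), (-1, 1), (1, -1), (1, 1))


@dataclasses.dataclass
class VascularNode:
    id: int
    position: tuple[float, float]  # (row, col)
    degree: int = 0
    node_kind: str = "endpoint"  # "bifurcation" | "endpoint"
    pixels: tuple = dataclasses.field(default=(), repr=False)


@dataclasses.dataclass(eq=False)
class VascularEdge:
    u: int
    v: int
    path: np.ndarray  # (k, 2) pixel polyline from u to v
    d_vp: float
    d_e: float
    a1: float = 0.0
    a2: float = 0.0

    @property
    def endpoints(self) -> tuple[int, int]:
        return (self.u, self.v)


@dataclasses.dataclass
class VascularGraph:
    nodes: dict[int, VascularNode]
    edges: list[VascularEdge]
    source_shape: tuple[int, int]

    # -- queries -----------------------------------------------------------

    def neighbors(self, node_id: int) -> list[int]:
        out = []
        for e in self.edges:
            if e.u == node_id:
                out.append(e.v)
            elif e.v == node_id:
                out.append(e.u)
        return sorted(set(out))

    def edge_between(self, u: int, v: int) -> VascularEdge | None:
        for e in self.edges:
            if {e.u, e.v} == {u, v}:
                return e
        return None

    def degree(self, node_id: int) -> int:
        return sum(1 for e in self.edges if node_id in (e.u, e.v))

    def positions(self, node_ids=None) -> np.ndarray:
        ids = list(self.nodes) if node_ids is None else list(node_ids)
        return np.array([self.nodes[i].position for i in ids], dtype=float)

    @property
    def node_ids(self) -> list[int]:
        return sorted(self.nodes)

    def to_networkx(self):
        import networkx as nx

        g = nx.MultiGraph()
        for n in self.nodes.values():
            g.add_node(n.id, position=n.position, node_kind=n.node_kind)
        for e in self.edges:
            g.add_edge(e.u, e.v, d_vp=e.d_vp, d_e=e.d_e, a1=e.a1, a2=e.a2)
        return g

    # -- serialization -----------------------------------------------------

    def to_dict(self, include_paths: bool = True) -> dict:
        return {
            "coordinate_convention": "(row, col), 0-based",
            "source_shape": list(self.source_shape),
            "nodes": [{"id": n.id, "position": list(n.position),
                       "degree": n.degree, "node_kind": n.node_kind}
                      for n in sorted(self.nodes.values(), key=lambda n: n.id)],
            "edges": [{"u": e.u, "v": e.v,
                       "path": np.asarray(e.path).tolist() if include_paths else None,
                       "d_vp": e.d_vp, "d_e": e.d_e, "a1": e.a1, "a2": e.a2}
                      for e in self.edges],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VascularGraph":
        nodes = {n["id"]: VascularNode(n["id"], tuple(n["position"]),
                                       n["degree"], n["node_kind"])
                 for n in d["nodes"]}
        edges = []
        for e in d["edges"]:
            path = np.asarray(e["path"], dtype=float) if e["path"] is not None \
                else np.array([nodes[e["u"]].position, nodes[e["v"]].position])
            edges.append(VascularEdge(e["u"], e["v"], path, e["d_vp"],
                                      e["d_e"], e["a1"], e["a2"]))
        return cls(nodes, edges, tuple(d["source_shape"]))

    def save_json(self, path, include_paths: bool = True) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(include_paths=include_paths), fh)

    @classmethod
    def load_json(cls, path) -> "VascularGraph":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def save_graphml(self, path) -> None:
        import networkx as nx

        g = nx.MultiGraph()
        for n in self.nodes.values():
            g.add_node(n.id, row=float(n.position[0]), col=float(n.position[1]),
                       node_kind=n.node_kind)
        for e in self.edges:
            g.add_edge(e.u, e.v, d_vp=e.d_vp, d_e=e.d_e, a1=e.a1, a2=e.a2)
        nx.write_graphml(g, path)


# ---------------------------------------------------------------------------
# feature point detection


def _crossing_number(mask: np.ndarray) -> np.ndarray:
    """Number of 0->1 transitions around each pixel's 8-neighborhood ring."""
    padded = np.pad(mask.astype(np.uint8), 1)
    ring = np.stack([padded[1 + dr:padded.shape[0] - 1 + dr,
                            1 + dc:padded.shape[1] - 1 + dc]
                     for dr, dc in _RING])
    nxt = np.roll(ring, -1, axis=0)
    return ((ring == 0) & (nxt == 1)).sum(axis=0)


def detect_feature_points(skeleton: CenterlineImage) -> list[VascularNode]:
    """Bifurcation and endpoint nodes of a one-pixel skeleton.

    A skeleton pixel with >= 3 branch transitions in its 3x3 ring is a
    bifurcation candidate; adjacent candidates are merged into one node at
    the cluster centroid snapped to the nearest member pixel.  Pixels with
    exactly one branch are endpoints.  Isolated pixels are ignored.
    """
    mask = np.asarray(skeleton.mask, dtype=bool)
    if not mask.any():
        return []
    cn = _crossing_number(mask)
    cn[~mask] = 0
    nodes: list[tuple[tuple[float, float], str, tuple]] = []

    bif = (cn >= 3) & mask
    labels, n_clusters = ndimage.label(bif, structure=np.ones((3, 3), int))
    for k in range(1, n_clusters + 1):
        members = np.argwhere(labels == k)
        centroid = members.mean(axis=0)
        snap = members[np.argmin(((members - centroid) ** 2).sum(axis=1))]
        nodes.append(((float(snap[0]), float(snap[1])), "bifurcation",
                      tuple(map(tuple, members))))

    for r, c in np.argwhere((cn == 1) & mask):
        nodes.append(((float(r), float(c)), "endpoint", (((int(r), int(c))),)))

    nodes.sort(key=lambda t: t[0])
    return [VascularNode(i, pos, 0, kind, px)
            for i, (pos, kind, px) in enumerate(nodes)]


# ---------------------------------------------------------------------------
# edge tracing


def _arc_length(path: np.ndarray) -> float:
    diffs = np.diff(np.asarray(path, dtype=float), axis=0)
    return float(np.sqrt((diffs ** 2).sum(axis=1)).sum())


def trace_edges(skeleton: CenterlineImage,
                nodes: list[VascularNode]) -> list[VascularEdge]:
    """Breadth-first walks along the skeleton from every node.

    Each walk starts at a node cluster pixel, follows unvisited skeleton
    pixels, and terminates at the first pixel belonging to another node,
    yielding one edge per vessel segment.  ``d_vp`` accumulates 1 per axial
    and sqrt(2) per diagonal step; ``d_e`` is the Euclidean distance between
    the two node positions.  Self-loops and node-free cycles are dropped and
    logged.
    """
    mask = np.asarray(skeleton.mask, dtype=bool)
    skel = {tuple(p) for p in np.argwhere(mask)}
    node_of: dict[tuple[int, int], int] = {}
    for n in nodes:
        for p in n.pixels:
            node_of[p] = n.id
    visited: set[tuple[int, int]] = set()
    edges: list[VascularEdge] = []
    seen_adjacent: set[tuple[int, int]] = set()

    def step(p, q):
        return 1.0 if (p[0] == q[0] or p[1] == q[1]) else np.sqrt(2.0)

    for node in sorted(nodes, key=lambda n: n.id):
        for p in sorted(node.pixels):
            for dr, dc in _NBRS:
                q = (p[0] + dr, p[1] + dc)
                if q not in skel:
                    continue
                if q in node_of:
                    other = node_of[q]
                    if other != node.id:
                        key = (min(node.id, other), max(node.id, other))
                        if key not in seen_adjacent:
                            seen_adjacent.add(key)
                            edges.append(_make_edge(node.id, other,
                                                    [p, q], nodes))
                    continue
                if q in visited:
                    continue
                edge = _walk(p, q, node.id, skel, node_of, visited, nodes, step)
                if edge is not None:
                    edges.append(edge)

    leftover = len([p for p in skel if p not in visited and p not in node_of])
    if leftover:
        log.debug("dropped %d skeleton pixels on node-free cycles/artifacts",
                  leftover)
    degrees: dict[int, int] = {n.id: 0 for n in nodes}
    for e in edges:
        degrees[e.u] += 1
        degrees[e.v] += 1
    for n in nodes:
        n.degree = degrees[n.id]
    return edges


def _make_edge(u: int, v: int, path, nodes) -> VascularEdge:
    pos = {n.id: n.position for n in nodes}
    full = [pos[u]] + [tuple(map(float, p)) for p in path] + [pos[v]]
    # drop duplicated endpoints when node position coincides with path ends
    cleaned = [full[0]]
    for p in full[1:]:
        if p != cleaned[-1]:
            cleaned.append(p)
    arr = np.asarray(cleaned, dtype=float)
    d_vp = _arc_length(arr)
    d_e = float(np.hypot(pos[u][0] - pos[v][0], pos[u][1] - pos[v][1]))
    return VascularEdge(u, v, arr, d_vp, d_e)


def _walk(p, q, start_id, skel, node_of, visited, nodes, step):
    path = [p, q]
    visited.add(q)
    prev, cur = p, q
    while True:
        terminal = None
        candidates = []
        for dr, dc in _NBRS:
            t = (cur[0] + dr, cur[1] + dc)
            if t not in skel or t == prev:
                continue
            if t in node_of:
                # avoid immediately re-entering the start cluster
                if node_of[t] == start_id and len(path) < 4:
                    continue
                if terminal is None:
                    terminal = t
            elif t not in visited:
                candidates.append(t)
        if terminal is not None:
            path.append(terminal)
            end_id = node_of[terminal]
            if end_id == start_id:
                log.debug("dropping self-loop at node %d", start_id)
                return None
            return _make_edge(start_id, end_id, path, nodes)
        if not candidates:
            log.debug("dangling walk from node %d dropped", start_id)
            return None
        # _NBRS lists axial moves first, so corners are followed through
        # their corner pixel instead of being cut by a diagonal shortcut
        nxt = candidates[0]
        visited.add(nxt)
        path.append(nxt)
        prev, cur = cur, nxt


# ---------------------------------------------------------------------------
# attribute normalization and pruning


def normalize_attributes(graph: VascularGraph) -> VascularGraph:
    """Set a1 = d_vp / mean(d_vp) and a2 = d_e / mean(d_e) over all edges."""
    if not graph.edges:
        raise EmptyGraphError("cannot normalize a graph without edges")
    mean_vp = float(np.mean([e.d_vp for e in graph.edges]))
    mean_e = float(np.mean([e.d_e for e in graph.edges]))
    if mean_vp <= 0 or mean_e <= 0:
        raise EmptyGraphError("degenerate edge lengths")
    for e in graph.edges:
        e.a1 = e.d_vp / mean_vp
        e.a2 = e.d_e / mean_e
    return graph


def prune_graph(graph: VascularGraph, min_edge_px: float = 10.0) -> VascularGraph:
    """Topological cleanup of skeletonization artifacts, then renormalize.

    Three rules are applied to a fixed point: (1) edges shorter than
    ``min_edge_px`` with a degree-1 endpoint (spurs) are deleted together
    with that endpoint; (2) short edges between two interior nodes are
    contracted, merging the two nodes (junction clusters split by the
    skeleton); (3) nodes left with exactly two incident edges are dissolved
    by concatenating the edges (``d_vp`` adds, ``d_e`` is recomputed).
    Isolated nodes are dropped; raises ``EmptyGraphError`` if nothing
    survives.
    """
    if min_edge_px < 0:
        raise ParameterError("min_edge_px must be >= 0")
    nodes = {i: dataclasses.replace(n) for i, n in graph.nodes.items()}
    edges = [dataclasses.replace(e, path=np.asarray(e.path, dtype=float).copy())
             for e in graph.edges]

    def degree_map():
        deg: dict[int, int] = {}
        for e in edges:
            deg[e.u] = deg.get(e.u, 0) + 1
            deg[e.v] = deg.get(e.v, 0) + 1
        return deg

    def recompute_de(e: VascularEdge):
        pu, pv = nodes[e.u].position, nodes[e.v].position
        e.d_e = float(np.hypot(pu[0] - pv[0], pu[1] - pv[1]))

    changed = True
    while changed and edges:
        changed = False
        deg = degree_map()
        # rule 1: short leaf spurs
        for e in list(edges):
            if e.d_vp < min_edge_px and (deg.get(e.u) == 1 or deg.get(e.v) == 1):
                edges.remove(e)
                changed = True
        if changed:
            continue
        # rule 2: contract short interior edges (split junction clusters)
        for e in list(edges):
            if e.d_vp >= min_edge_px or deg.get(e.u, 0) < 2 \
                    or deg.get(e.v, 0) < 2:
                continue
            keep, drop = e.u, e.v
            edges.remove(e)
            for other in list(edges):
                if other.u == drop:
                    other.u = keep
                if other.v == drop:
                    other.v = keep
                if other.u == other.v:
                    edges.remove(other)  # became a self-loop
                else:
                    recompute_de(other)
            changed = True
            break
        if changed:
            continue
        # rule 3: dissolve degree-2 nodes
        deg = degree_map()
        for nid, d in deg.items():
            if d != 2:
                continue
            inc = [e for e in edges if nid in (e.u, e.v)]
            if len(inc) != 2 or inc[0] is inc[1]:
                continue
            e1, e2 = inc
            far1 = e1.v if e1.u == nid else e1.u
            far2 = e2.v if e2.u == nid else e2.u
            if far1 == far2 or far1 == nid or far2 == nid:
                continue
            p1 = e1.path if e1.v == nid else e1.path[::-1]
            p2 = e2.path if e2.u == nid else e2.path[::-1]
            merged = VascularEdge(far1, far2, np.vstack([p1, p2[1:]]),
                                  e1.d_vp + e2.d_vp, 0.0)
            recompute_de(merged)
            edges.remove(e1)
            edges.remove(e2)
            edges.append(merged)
            changed = True
            break

    if not edges:
        raise EmptyGraphError("pruning removed every edge")
    used = {e.u for e in edges} | {e.v for e in edges}
    nodes = {i: n for i, n in nodes.items() if i in used}
    for n in nodes.values():
        n.degree = sum(1 for e in edges if n.id in (e.u, e.v))
        n.node_kind = "bifurcation" if n.degree >= 3 else "endpoint"
    pruned = VascularGraph(nodes, edges, graph.source_shape)
    return normalize_attributes(pruned)


def build_graph(skeleton: CenterlineImage, min_edge_px: float = 10.0,
                source_shape: tuple[int, int] | None = None) -> VascularGraph:
    """Detect feature points, trace segments, prune and normalize."""
    nodes = detect_feature_points(skeleton)
    edges = trace_edges(skeleton, nodes)
    shape = source_shape or tuple(skeleton.mask.shape)
    graph = VascularGraph({n.id: n for n in nodes if n.degree > 0},
                          edges, shape)
    if not graph.edges:
        raise EmptyGraphError("no vessel segments traced")
    normalize_attributes(graph)
    if min_edge_px > 0:
        graph = prune_graph(graph, min_edge_px)
    return graph
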