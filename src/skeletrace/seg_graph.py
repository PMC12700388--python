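"""Spatially embedded graphs (SEGs) over skeleton point clouds.

Nodes carry 3D voxel coordinates, edges Euclidean lengths.  The pipeline is:
connect points closer than an epsilon-ball radius, remove cycles with a
minimum spanning forest, split branch nodes so every component becomes a
simple path (one filament instance), then read the paths off as ordered
curves.  Branch splitting keeps the edge pair forming the largest angle —
the straightest continuation — and moves every other edge onto a duplicate
node at the same position, so edge count is conserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from networkx.utils import UnionFind
from scipy.spatial import cKDTree

from .errors import ParameterError
from .nms import SkeletonCloud

__all__ = [
    "SpatialGraph",
    "Curve",
    "build_graph",
    "spanning_forest",
    "split_filaments",
    "extract_curves",
]


@dataclass
class SpatialGraph:
    """Undirected graph whose nodes have a ``pos`` attribute (voxel units)
    and whose edges have a ``length`` attribute (Euclidean distance)."""

    graph: nx.Graph = field(default_factory=nx.Graph)
    voxel_size: float = 1.0

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def positions(self) -> dict[int, np.ndarray]:
        return {n: np.asarray(d["pos"], dtype=float) for n, d in self.graph.nodes(data=True)}

    def total_length(self) -> float:
        return float(sum(d["length"] for _, _, d in self.graph.edges(data=True)))

    def max_degree(self) -> int:
        if self.n_nodes == 0:
            return 0
        return max(d for _, d in self.graph.degree)


@dataclass
class Curve:
    """Ordered 3D point sequence of one filament (voxel units)."""

    points: np.ndarray
    voxel_size: float = 1.0

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 2:
            raise ParameterError("a curve needs an (n>=2, 3) point array")
        if np.any(np.all(pts[1:] == pts[:-1], axis=1)):
            raise ParameterError("consecutive curve points must be distinct")
        self.points = pts

    def __len__(self) -> int:
        return len(self.points)

    @property
    def length_nm(self) -> float:
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return float(seg.sum() * self.voxel_size)


def build_graph(cloud: SkeletonCloud, epsilon: float) -> SpatialGraph:
    """Epsilon-ball graph: an edge for every pair at distance strictly < eps.

    Exactly coincident points are merged (first occurrence kept) so that no
    zero-length edge can arise.  Neighbor search uses a k-d tree.
    """
    if epsilon <= 0:
        raise ParameterError(f"epsilon must be > 0, got {epsilon}")
    pts = np.asarray(cloud.points, dtype=float)
    if len(pts):
        _, first = np.unique(pts, axis=0, return_index=True)
        pts = pts[np.sort(first)]
    g = nx.Graph()
    for i, p in enumerate(pts):
        g.add_node(i, pos=p.copy())
    if len(pts) > 1:
        tree = cKDTree(pts)
        for i, j in sorted(tree.query_pairs(r=epsilon)):
            d = float(np.linalg.norm(pts[i] - pts[j]))
            if d < epsilon:  # k-d tree query is <=; the criterion is strict
                g.add_edge(i, j, length=d)
    return SpatialGraph(g, cloud.voxel_size)


def spanning_forest(g: SpatialGraph) -> SpatialGraph:
    """Minimum spanning forest (Kruskal), removing all cycles.

    Ties in edge weight are broken deterministically by (weight, smaller node
    id, larger node id).
    """
    out = nx.Graph()
    out.add_nodes_from(g.graph.nodes(data=True))
    edges = sorted(
        (
            (d["length"], min(u, v), max(u, v))
            for u, v, d in g.graph.edges(data=True)
        )
    )
    uf = UnionFind(g.graph.nodes)
    for w, u, v in edges:
        if uf[u] != uf[v]:
            uf.union(u, v)
            out.add_edge(u, v, length=w)
    return SpatialGraph(out, g.voxel_size)


def _angle(pi: np.ndarray, pp: np.ndarray, pq: np.ndarray) -> float:
    """Angle at pi between directions toward pp and pq, in radians."""
    a = pp - pi
    b = pq - pi
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(np.arccos(np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0)))


def split_filaments(g: SpatialGraph) -> SpatialGraph:
    """Split every branch node so each component becomes a simple path.

    For a node of degree ``m > 2`` the edge pair subtending the largest angle
    is kept (ties: first pair in ascending edge-index order); each of the
    remaining ``m - 2`` edges is re-attached to a fresh duplicate node at the
    same coordinates.  Requires an acyclic input graph.
    """
    if not nx.is_forest(g.graph):
        raise ParameterError("split_filaments requires an acyclic graph")
    out = g.graph.copy()
    next_id = (max(out.nodes) + 1) if out.number_of_nodes() else 0
    for n in sorted(g.graph.nodes):
        if out.degree(n) <= 2:
            continue
        pos_i = np.asarray(out.nodes[n]["pos"], dtype=float)
        nbrs = list(out.neighbors(n))
        best = (0, 1)
        best_angle = -1.0
        for j in range(len(nbrs)):
            for k in range(j + 1, len(nbrs)):
                ang = _angle(
                    pos_i,
                    np.asarray(out.nodes[nbrs[j]]["pos"], dtype=float),
                    np.asarray(out.nodes[nbrs[k]]["pos"], dtype=float),
                )
                if ang > best_angle:
                    best_angle = ang
                    best = (j, k)
        for idx, nb in enumerate(nbrs):
            if idx in best:
                continue
            length = out.edges[n, nb]["length"]
            out.remove_edge(n, nb)
            out.add_node(next_id, pos=pos_i.copy())
            out.add_edge(next_id, nb, length=length)
            next_id += 1
    return SpatialGraph(out, g.voxel_size)


def extract_curves(g: SpatialGraph, min_length: float = 0.0) -> list[Curve]:
    """Ordered curves, one per path component with at least two nodes.

    Each curve starts at the endpoint with lexicographically smaller
    coordinates.  Curves with geodesic length (nm) below ``min_length`` and
    singleton nodes are discarded.
    """
    if g.max_degree() > 2:
        raise ParameterError("extract_curves requires max degree <= 2")
    if not nx.is_forest(g.graph):
        raise ParameterError("extract_curves requires an acyclic graph")
    curves = []
    for comp in nx.connected_components(g.graph):
        if len(comp) < 2:
            continue
        sub = g.graph.subgraph(comp)
        ends = [n for n in comp if sub.degree(n) == 1]
        keyed = sorted(ends, key=lambda n: tuple(sub.nodes[n]["pos"]))
        path = [keyed[0]]
        prev = None
        while True:
            nxt = [n for n in sub.neighbors(path[-1]) if n != prev]
            if not nxt:
                break
            prev = path[-1]
            path.append(nxt[0])
        pts = np.asarray([sub.nodes[n]["pos"] for n in path], dtype=float)
        curve = Curve(pts, g.voxel_size)
        if curve.length_nm >= min_length:
            curves.append(curve)
    curves.sort(key=lambda c: tuple(c.points[0]))
    return curves


def label_filaments(g: SpatialGraph) -> SpatialGraph:
    """Assign a ``filament_id`` node attribute per connected component."""
    for fid, comp in enumerate(nx.connected_components(g.graph)):
        for n in comp:
            g.graph.nodes[n]["filament_id"] = fid
    return g
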