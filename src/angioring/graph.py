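"""Geometric junction graph of a vessel network.

The twelve assay parameters that involve topology (junctions, loops) are
defined on an undirected graph whose edges are vessel segments and whose
nodes are attachment points, tips, and anastomosis points.  Because networks
are traced or simulated in continuous coordinates, nearby endpoints must be
merged into a single node: attachment points closer than ``merge_tol`` (um)
are one junction.

A segment is split into chain edges at every node that lies on it (its own
endpoints, the attachment points of its children, and any anastomosing tip),
so cycles that pass *through* the middle of a segment are represented
correctly.  Each chain edge carries the id of the segment it belongs to;
loop counting then asks how many *distinct segments* a cycle spans.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .model import VesselNetwork

__all__ = ["JunctionGraph", "build_junction_graph", "DEFAULT_MERGE_TOL"]

DEFAULT_MERGE_TOL = 5.0  # um; the assay's manual tracing has no sub-5-um precision


def _project_to_polyline(
    point: np.ndarray, poly: np.ndarray
) -> tuple[float, float, np.ndarray]:
    """Distance to a polyline, arclength position and coordinates of the foot."""
    p = np.asarray(point, dtype=float)
    a = poly[:-1]
    b = poly[1:]
    ab = b - a
    seg_len = np.linalg.norm(ab, axis=1)
    seg_len_safe = np.where(seg_len == 0, 1.0, seg_len)
    t = np.clip(np.einsum("ij,ij->i", p - a, ab) / seg_len_safe**2, 0.0, 1.0)
    foot = a + t[:, None] * ab
    d = np.linalg.norm(foot - p, axis=1)
    i = int(np.argmin(d))
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    return float(d[i]), float(cum[i] + t[i] * seg_len[i]), foot[i]


@dataclass
class JunctionGraph:
    graph: nx.Graph  # chain graph; edge attrs: segment (id), length (um)
    node_pos: dict[int, np.ndarray]
    junction_nodes: set[int]  # nodes where >=1 branch attaches
    root_nodes: set[int]  # nodes where an initial vessel leaves the ring
    merge_tol: float
    warnings: list[str] = field(default_factory=list)


def build_junction_graph(
    net: VesselNetwork, merge_tol: float = DEFAULT_MERGE_TOL
) -> JunctionGraph:
    """Build the merged junction graph of a network.

    Anastomoses are discovered geometrically: a segment tip lying within
    ``merge_tol`` of another segment's polyline (other than its own parent's
    attachment neighbourhood) is fused onto that segment.
    """
    segs = list(net.segments.values())
    if not segs:
        return JunctionGraph(nx.Graph(), {}, set(), set(), merge_tol)

    # --- candidate node points ------------------------------------------------
    # (point, tags) where tags mark roles: root / attach-of-branch / tip
    points: list[np.ndarray] = []
    roles: list[tuple[str, str]] = []  # (role, segment_id)
    # split positions per segment: seg_id -> list of (arclength, point_index)
    splits: dict[str, list[tuple[float, int]]] = {s.id: [] for s in segs}

    def add_point(pt: np.ndarray, role: str, seg_id: str) -> int:
        points.append(np.asarray(pt, dtype=float))
        roles.append((role, seg_id))
        return len(points) - 1

    cumlen: dict[str, np.ndarray] = {}
    for s in segs:
        d = np.linalg.norm(np.diff(s.polyline, axis=0), axis=1)
        cumlen[s.id] = np.concatenate([[0.0], np.cumsum(d)])

    for s in segs:
        i0 = add_point(s.polyline[0], "root" if s.kind == "initial" else "attach", s.id)
        i1 = add_point(s.polyline[-1], "tip", s.id)
        splits[s.id].append((0.0, i0))
        splits[s.id].append((float(cumlen[s.id][-1]), i1))

    # child attachment points split their parent
    for s in segs:
        if s.kind == "branch":
            parent = net.segments[s.parent_id]
            dist, pos, _foot = _project_to_polyline(s.attach_point, parent.polyline)
            idx = add_point(s.attach_point, "on_parent", parent.id)
            splits[parent.id].append((pos, idx))

    # anastomosing tips split their target segment
    all_vertices = np.vstack([s.polyline for s in segs])
    vert_seg = np.concatenate([[s.id] * len(s.polyline) for s in segs])
    tree = cKDTree(all_vertices)
    max_edge = max(
        float(np.max(np.linalg.norm(np.diff(s.polyline, axis=0), axis=1))) for s in segs
    )
    for s in segs:
        tip = s.tip
        cand = tree.query_ball_point(tip, merge_tol + max_edge)
        cand_segs = {vert_seg[i] for i in cand} - {s.id}
        best = None
        for sid in cand_segs:
            other = net.segments[sid]
            dist, pos, _foot = _project_to_polyline(tip, other.polyline)
            if dist <= merge_tol:
                # ignore a "fusion" right at the target's shared endpoint with us
                if best is None or dist < best[0]:
                    best = (dist, pos, sid)
        if best is not None:
            _, pos, sid = best
            idx = add_point(tip, "fusion", sid)
            splits[sid].append((pos, idx))

    # --- merge nearby points into nodes --------------------------------------
    pts = np.asarray(points)
    ptree = cKDTree(pts)
    parent_uf = list(range(len(pts)))

    def find(i: int) -> int:
        while parent_uf[i] != i:
            parent_uf[i] = parent_uf[parent_uf[i]]
            i = parent_uf[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent_uf[rj] = ri

    for i, j in ptree.query_pairs(merge_tol):
        union(i, j)

    node_of_point = {i: find(i) for i in range(len(pts))}
    node_pos: dict[int, np.ndarray] = {}
    for i in range(len(pts)):
        r = node_of_point[i]
        node_pos.setdefault(r, pts[r])

    # --- chain graph ----------------------------------------------------------
    g = nx.MultiGraph()
    for s in segs:
        entries = sorted(splits[s.id], key=lambda e: e[0])
        chain: list[tuple[float, int]] = []
        for pos, idx in entries:
            nid = node_of_point[idx]
            if chain and chain[-1][1] == nid:
                continue
            chain.append((pos, nid))
        for (p0, n0), (p1, n1) in zip(chain[:-1], chain[1:]):
            g.add_edge(n0, n1, segment=s.id, length=max(p1 - p0, 0.0))

    junction_nodes = {
        node_of_point[i] for i, (role, _) in enumerate(roles) if role == "attach"
    }
    root_nodes = {
        node_of_point[i] for i, (role, _) in enumerate(roles) if role == "root"
    }

    return JunctionGraph(g, node_pos, junction_nodes, root_nodes, merge_tol)


def count_independent_loops(jg: JunctionGraph, min_segments: int = 3) -> int:
    """Number of independent cycles spanning >= ``min_segments`` segments.

    Parallel chain edges are resolved by inserting a midpoint pseudo-node so
    a simple graph carries the full cycle space; a fundamental cycle basis is
    then computed and each basis cycle is kept only if it runs through at
    least ``min_segments`` distinct vessel segments.
    """
    g = jg.graph
    simple = nx.Graph()
    simple.add_nodes_from(g.nodes)
    pseudo = -1
    for u, v, k, data in g.edges(keys=True, data=True):
        if u == v:
            continue  # a self-loop chain edge spans a single segment: never >=3
        if simple.has_edge(u, v):
            simple.add_edge(u, pseudo, **data)
            simple.add_edge(pseudo, v, **data)
            pseudo -= 1
        else:
            simple.add_edge(u, v, **data)
    count = 0
    for cycle in nx.cycle_basis(simple):
        seg_ids = set()
        n = len(cycle)
        for i in range(n):
            u, v = cycle[i], cycle[(i + 1) % n]
            seg_ids.add(simple.edges[u, v]["segment"])
        if len(seg_ids) >= min_segments:
            count += 1
    return count
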