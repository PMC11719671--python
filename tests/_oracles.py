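"""Independent brute-force oracles for the assay parameters.

Deliberately written with plain Python loops and closed forms, separate
from the package implementation, so tests compare two independent routes
to each quantity.  Random networks are built constructively: every count
(vessels, branches, junctions, loops) is known because the builder put it
there, never because it was measured.
"""

from __future__ import annotations

import math

import numpy as np

from angioring import RingExplant, VesselNetwork, VesselSegment


def brute_length(points) -> float:
    total = 0.0
    for a, b in zip(points[:-1], points[1:]):
        total += math.hypot(b[0] - a[0], b[1] - a[1])
    return total


def brute_structure_pct(net: VesselNetwork) -> float:
    n_init = sum(1 for s in net.segments.values() if s.kind == "initial")
    return 100.0 * n_init / len(net.segments)


def brute_total_mean(net: VesselNetwork) -> tuple[float, float]:
    lengths = [brute_length(s.polyline) for s in net.segments.values()]
    return sum(lengths), sum(lengths) / len(lengths)


def brute_max_initial(net: VesselNetwork) -> float:
    return max(
        brute_length(s.polyline)
        for s in net.segments.values()
        if s.kind == "initial"
    )


def brute_radial_circle(net: VesselNetwork) -> float:
    """Max perpendicular tip-to-boundary distance, closed form for a circle."""
    cx, cy = net.ring.center
    r = net.ring.radius
    best = 0.0
    for s in net.segments.values():
        x, y = s.polyline[-1]
        best = max(best, abs(math.hypot(x - cx, y - cy) - r))
    return best


def brute_radial_sampled(net: VesselNetwork, n: int = 200_000) -> float:
    """Max tip-to-boundary distance by dense boundary sampling."""
    cx, cy = net.ring.center
    r = net.ring.radius
    theta = np.linspace(0.0, 2.0 * math.pi, n, endpoint=False)
    bx = cx + r * np.cos(theta)
    by = cy + r * np.sin(theta)
    best = 0.0
    for s in net.segments.values():
        x, y = s.polyline[-1]
        d = np.sqrt((bx - x) ** 2 + (by - y) ** 2).min()
        best = max(best, float(d))
    return best


def brute_density(net: VesselNetwork) -> tuple[int, float]:
    count = sum(1 for s in net.segments.values() if s.kind == "initial")
    return count, count / (net.ring.circumference / 1000.0)


def brute_branch_stats(net: VesselNetwork) -> tuple[int, float]:
    lengths = [
        brute_length(s.polyline) for s in net.segments.values() if s.kind == "branch"
    ]
    if not lengths:
        return 0, float("nan")
    return len(lengths), sum(lengths) / len(lengths)


def brute_junctions(net: VesselNetwork, tol: float = 5.0) -> int:
    """O(n^2) clustering of branch attachment points into junction nodes."""
    pts = [tuple(s.polyline[0]) for s in net.segments.values() if s.kind == "branch"]
    clusters: list[list[tuple[float, float]]] = []
    for p in pts:
        placed = False
        for cl in clusters:
            if any(math.hypot(p[0] - q[0], p[1] - q[1]) <= tol for q in cl):
                cl.append(p)
                placed = True
                break
        if not placed:
            clusters.append([p])
    return len(clusters)


# --------------------------------------------------------------------------
# constructive random networks with ground truth known by construction


def _point_at(poly: np.ndarray, frac: float) -> tuple[np.ndarray, np.ndarray]:
    """Point at a fraction of a polyline's arclength, and local direction."""
    d = np.linalg.norm(np.diff(poly, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(d)])
    s = frac * cum[-1]
    i = int(np.searchsorted(cum, s, side="right") - 1)
    i = min(i, len(poly) - 2)
    t = (s - cum[i]) / max(d[i], 1e-12)
    pt = poly[i] + t * (poly[i + 1] - poly[i])
    direction = (poly[i + 1] - poly[i]) / max(d[i], 1e-12)
    return pt, direction


def build_random_network(
    rng: np.random.Generator,
    max_segments: int = 20,
    n_loops: int = 0,
    min_node_sep: float = 15.0,
):
    """Random rooted network plus its ground-truth summary.

    Returns ``(net, truth)`` where ``truth`` holds counts and lengths that
    are correct by construction: initial/branch counts, one junction per
    branch attachment (all attachment points are kept mutually separated),
    and ``n_loops`` closed circuits each spanning four segments.
    """
    from shapely.geometry import LineString, Point

    ring = RingExplant(radius=float(rng.uniform(400, 600)))
    net = VesselNetwork(ring=ring, segments={})
    nodes: list[np.ndarray] = []

    def far_from_nodes(p) -> bool:
        return all(np.linalg.norm(p - q) > min_node_sep for q in nodes)

    def far_from_lines(p, clearance: float = 8.0) -> bool:
        # free tips must not graze an unrelated vessel, which the junction
        # merger would read as an (unintended) anastomosis
        q = Point(p)
        return all(
            LineString(s.polyline).distance(q) > clearance
            for s in net.segments.values()
        )

    tips: list[np.ndarray] = []

    def line_clear_of_tips(polyline, clearance: float = 8.0) -> bool:
        # ... and a new vessel must not graze an existing free tip either
        line = LineString(polyline)
        return all(line.distance(Point(t)) > clearance for t in tips)

    n_init = int(rng.integers(1, 5))
    counter = 0

    def add(polyline, kind, parent) -> str:
        nonlocal counter
        sid = f"r{counter:03d}"
        counter += 1
        net.segments[sid] = VesselSegment(
            id=sid, polyline=np.asarray(polyline, float), kind=kind, parent_id=parent
        )
        return sid

    for _ in range(n_init):
        for _try in range(50):
            a = float(rng.uniform(0, 2 * math.pi))
            p0 = ring.boundary_point(a)
            direction = np.array([math.cos(a), math.sin(a)])
            length = rng.uniform(150, 500)
            # a gentle dog-leg so polylines are not always two points
            mid = p0 + 0.5 * length * direction
            rot = rng.uniform(-0.3, 0.3)
            d2 = np.array([math.cos(a + rot), math.sin(a + rot)])
            tip = mid + 0.5 * length * d2
            if not (far_from_nodes(p0) and far_from_nodes(tip)):
                continue
            if not (far_from_lines(tip) and far_from_lines(mid)):
                continue
            if not line_clear_of_tips([p0, mid, tip]):
                continue
            add([p0, mid, tip], "initial", None)
            nodes.extend([p0, tip])
            tips.append(tip)
            break

    n_branches = int(rng.integers(0, max(1, max_segments - n_init - 4 * n_loops + 1)))
    truth_branches = 0
    for _ in range(n_branches):
        for _try in range(30):
            parent = rng.choice(list(net.segments))
            ppoly = net.segments[parent].polyline
            attach, pdir = _point_at(ppoly, float(rng.uniform(0.2, 0.8)))
            if not far_from_nodes(attach):
                continue
            ang = math.atan2(pdir[1], pdir[0]) + rng.choice([-1, 1]) * math.radians(
                rng.uniform(35, 80)
            )
            length = rng.uniform(60, 160)
            tip = attach + length * np.array([math.cos(ang), math.sin(ang)])
            if not far_from_nodes(tip) or not far_from_lines(tip):
                continue
            if not line_clear_of_tips([attach, tip]):
                continue
            add([attach, tip], "branch", parent)
            nodes.extend([attach, tip])
            tips.append(tip)
            truth_branches += 1
            break

    truth_loops = 0
    for _ in range(n_loops):
        for _try in range(50):
            candidates = [
                s for s in net.segments.values() if brute_length(s.polyline) > 200
            ]
            if not candidates:
                break
            parent = rng.choice(candidates).id
            ppoly = net.segments[parent].polyline
            f1, f2 = sorted(rng.uniform(0.15, 0.85, size=2))
            if (f2 - f1) * brute_length(ppoly) < 2 * min_node_sep:
                continue
            a1, d1 = _point_at(ppoly, float(f1))
            a2, d2 = _point_at(ppoly, float(f2))
            if not (far_from_nodes(a1) and far_from_nodes(a2)):
                continue
            base = math.atan2(d1[1], d1[0])
            side = rng.choice([-1, 1])
            h = rng.uniform(60, 120)
            t1 = a1 + h * np.array(
                [math.cos(base + side * 1.0), math.sin(base + side * 1.0)]
            )
            t2 = a2 + h * np.array(
                [math.cos(base + side * 1.6), math.sin(base + side * 1.6)]
            )
            if not (far_from_nodes(t1) and far_from_nodes(t2)):
                continue
            if not (far_from_lines(t1) and far_from_lines(t2)):
                continue
            if not (line_clear_of_tips([a1, t1]) and line_clear_of_tips([a2, t2])
                    and line_clear_of_tips([t1, t2])):
                continue
            b1 = add([a1, t1], "branch", parent)
            b2 = add([a2, t2], "branch", parent)
            # closing branch fuses tip-to-tip: cycle b1 + parent + b2 + closing
            add([t1, t2], "branch", b1)
            nodes.extend([a1, a2, t1, t2])
            truth_branches += 3
            truth_loops += 1
            break

    net.validate()
    truth = {
        "n_initial": n_init,
        "n_branch": truth_branches,
        "n_junctions": truth_branches,  # every attachment point is distinct
        "n_loops": truth_loops,
        "total_length": brute_total_mean(net)[0],
    }
    return net, truth
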