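"""Domain types for explant vessel networks.

An aortic ring assay produces, per explant ("ring"), a rooted hierarchy of
microvessels: *initial* (primary) vessels sprout directly from the outer edge
of the ring, and *branches* sprout from initial vessels or from other
branches.  Anastomosis of a vessel tip with another vessel closes a *loop*.
All coordinates are continuous 2-D positions in micrometres with the origin
conventionally at the ring centre.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import LinearRing, Point

__all__ = [
    "InvalidGeometryError",
    "InconsistentNetworkError",
    "UndefinedParameterError",
    "RingExplant",
    "VesselSegment",
    "VesselNetwork",
    "ExplantObservation",
    "ParameterRecord",
    "polyline_length",
]


class InvalidGeometryError(ValueError):
    """Raised for degenerate geometric input (e.g. a <3-vertex boundary)."""


class InconsistentNetworkError(ValueError):
    """Raised when a network violates its structural invariants."""


class UndefinedParameterError(ValueError):
    """Raised when a parameter is undefined for the given network.

    Undefined is distinct from zero: a ring without branches has *no* mean
    branch length, not a mean branch length of 0.
    """


def polyline_length(points: np.ndarray) -> float:
    """Euclidean path length of an ordered point list (n, 2) in um."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise InvalidGeometryError("polyline needs at least 2 points")
    return float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))


@dataclass
class RingExplant:
    """The explanted aortic ring: centre plus outer boundary.

    The boundary is either a circle (``radius``) or an explicit simple closed
    polygon (``boundary``, shape (n, 2), vertices in order, not repeated at
    the end).  The outer circumference of the ring is the "explant" covariate
    used to normalise vessel counts to vessel density.
    """

    center: tuple[float, float] = (0.0, 0.0)
    radius: float | None = None
    boundary: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.boundary is not None:
            b = np.asarray(self.boundary, dtype=float)
            if b.ndim != 2 or b.shape[0] < 3 or b.shape[1] != 2:
                raise InvalidGeometryError(
                    "boundary polygon needs at least 3 (x, y) vertices"
                )
            ring = LinearRing(b)
            if not ring.is_valid or not ring.is_simple:
                raise InvalidGeometryError("boundary polygon is self-intersecting")
            self.boundary = b
            self._ring = ring
        elif self.radius is not None:
            if self.radius <= 0:
                raise InvalidGeometryError("ring radius must be positive")
            self._ring = None
        else:
            raise InvalidGeometryError("ring needs either a radius or a boundary")

    @property
    def circumference(self) -> float:
        """Outer circumference in um (polygon perimeter, or 2*pi*r)."""
        if self.boundary is not None:
            return float(self._ring.length)
        return 2.0 * math.pi * float(self.radius)

    def distance_to_boundary(self, points: np.ndarray) -> np.ndarray:
        """Shortest (perpendicular) distance from each point to the boundary."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if self.boundary is None:
            d = np.linalg.norm(pts - np.asarray(self.center), axis=1)
            return np.abs(d - float(self.radius))
        return np.array([self._ring.distance(Point(p)) for p in pts])

    def boundary_point(self, angle_rad: float) -> np.ndarray:
        """Point on a circular boundary at a given polar angle (circle only)."""
        if self.radius is None:
            raise InvalidGeometryError("boundary_point requires a circular ring")
        c = np.asarray(self.center, dtype=float)
        return c + self.radius * np.array([math.cos(angle_rad), math.sin(angle_rad)])


@dataclass
class VesselSegment:
    """One traced vessel: an ordered polyline from attachment to tip.

    ``kind`` is "initial" when the segment sprouts from the ring itself
    (``parent_id`` is None) and "branch" when it sprouts from another
    segment.  ``generation`` records branch depth (initial=0) but none of the
    twelve assay parameters uses it.
    """

    id: str
    polyline: np.ndarray
    kind: str  # "initial" | "branch"
    parent_id: str | None = None
    generation: int = 0

    def __post_init__(self) -> None:
        pts = np.asarray(self.polyline, dtype=float)
        if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 2:
            raise InvalidGeometryError(
                f"segment {self.id}: polyline needs >=2 (x, y) points"
            )
        self.polyline = pts
        if self.kind not in ("initial", "branch"):
            raise InconsistentNetworkError(f"segment {self.id}: unknown kind {self.kind!r}")
        if self.kind == "initial" and self.parent_id is not None:
            raise InconsistentNetworkError(
                f"segment {self.id}: initial vessels attach to the ring, not a parent"
            )
        if self.kind == "branch" and self.parent_id is None:
            raise InconsistentNetworkError(f"segment {self.id}: branch without parent")
        if polyline_length(pts) <= 0:
            raise InvalidGeometryError(f"segment {self.id}: zero length")

    @property
    def attach_point(self) -> np.ndarray:
        """Proximal end: on the ring (initial) or on the parent (branch)."""
        return self.polyline[0]

    @property
    def tip(self) -> np.ndarray:
        """Distal end (the growing/fused tip)."""
        return self.polyline[-1]

    @property
    def length(self) -> float:
        return polyline_length(self.polyline)


@dataclass
class VesselNetwork:
    """All vessels of one explant at one timepoint, rooted at the ring."""

    ring: RingExplant
    segments: dict[str, VesselSegment] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for seg in self.segments.values():
            if seg.kind == "branch" and seg.parent_id not in self.segments:
                raise InconsistentNetworkError(
                    f"segment {seg.id}: parent {seg.parent_id!r} not in network"
                )
        # parent links must form a forest rooted at the ring
        for seg in self.segments.values():
            seen = set()
            cur = seg
            while cur.parent_id is not None:
                if cur.id in seen:
                    raise InconsistentNetworkError("cycle in parent hierarchy")
                seen.add(cur.id)
                cur = self.segments[cur.parent_id]

    def add(self, seg: VesselSegment) -> None:
        self.segments[seg.id] = seg

    @property
    def initial_segments(self) -> list[VesselSegment]:
        return [s for s in self.segments.values() if s.kind == "initial"]

    @property
    def branch_segments(self) -> list[VesselSegment]:
        return [s for s in self.segments.values() if s.kind == "branch"]

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    @property
    def is_empty(self) -> bool:
        return not self.segments

    def tips(self) -> np.ndarray:
        """Distal endpoints of all segments, shape (n, 2)."""
        if self.is_empty:
            return np.empty((0, 2))
        return np.array([s.tip for s in self.segments.values()])


@dataclass
class ExplantObservation:
    """One ring imaged at one timepoint.

    ``imaging_time_h`` is hours since assay start (used for growth speeds;
    photo documentation days need not be exactly 24 h apart).  ``network`` may
    be None when only pre-measured parameters exist for this ring.
    """

    donor: str
    group: str
    ring_id: str
    day: int
    imaging_time_h: float
    network: VesselNetwork | None = None

    def __post_init__(self) -> None:
        if self.day <= 0:
            raise ValueError("day must be a positive integer")

    @property
    def migrated(self) -> bool:
        """Sprouting visible: at least one vessel has left the explant."""
        return self.network is not None and not self.network.is_empty


@dataclass
class ParameterRecord:
    """One tidy measurement: a named parameter of one ring at one day."""

    donor: str
    group: str
    ring_id: str
    day: int
    imaging_time_h: float
    parameter: str
    category: str
    value: float  # NaN encodes "undefined for this ring", never zero
    units: str
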