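"""The twelve operational parameters of the aortic ring assay.

Parameters fall into four subindex categories:

* **explant** — migration (sprouting visible), ring circumference;
* **pattern** — vessel structure (% primary vessels), number of loops;
* **network_properties** — maximum radial outgrowth, maximum initial vessel
  length, total and mean vessel length, growth speeds of the mean/max
  initial vessel length;
* **sprouting** — vessel count and density, branch number and mean length,
  junction count and junctions per vessel.

All length computations are plain polyline arithmetic; the topological ones
(junctions, loops) are defined on the merged junction graph (see
:mod:`angioring.graph`).  Parameters that are undefined for a ring (e.g. the
mean branch length of a ring without branches) are reported as missing, not
as zero — averaging zeros would conflate absence with short vessels.
"""

from __future__ import annotations

import math

import numpy as np

from .graph import DEFAULT_MERGE_TOL, build_junction_graph, count_independent_loops
from .model import (
    ExplantObservation,
    InconsistentNetworkError,
    InvalidGeometryError,
    ParameterRecord,
    RingExplant,
    UndefinedParameterError,
    VesselNetwork,
)

__all__ = [
    "PARAMETER_REGISTRY",
    "AUXILIARY_PARAMETERS",
    "CATEGORY_ORDER",
    "circumference",
    "vessel_structure_pct",
    "count_loops",
    "max_radial_outgrowth",
    "max_initial_vessel_length",
    "total_and_mean_vessel_length",
    "growth_speeds",
    "vessel_count_and_density",
    "branch_statistics",
    "junction_counts",
    "roi_extrapolate_endpoints",
    "vessel_area",
    "quantify",
]

CATEGORY_ORDER = ("explant", "pattern", "network_properties", "sprouting")

#: name -> (subindex category, units).  The twelve per-observation parameters
#: first, then the two interval (growth-speed) parameters which need a pair
#: of imaging timepoints and are attributed to the later day.
PARAMETER_REGISTRY: dict[str, tuple[str, str]] = {
    "migration": ("explant", "fraction"),
    "circumference": ("explant", "um"),
    "vessel_structure": ("pattern", "%"),
    "loop_count": ("pattern", "count"),
    "max_radial_outgrowth": ("network_properties", "um"),
    "max_initial_vessel_length": ("network_properties", "um"),
    "total_vessel_length": ("network_properties", "um"),
    "mean_vessel_length": ("network_properties", "um"),
    "vessel_density": ("sprouting", "count/mm"),
    "branch_count": ("sprouting", "count"),
    "mean_branch_length": ("sprouting", "um"),
    "junctions_per_vessel": ("sprouting", "count"),
    "speed_mean_initial_length": ("network_properties", "um/day"),
    "speed_max_initial_length": ("network_properties", "um/day"),
}

#: companion values exposed by the same operations (not part of the 12-record
#: per-observation set but available on request)
AUXILIARY_PARAMETERS: dict[str, tuple[str, str]] = {
    "vessel_count": ("sprouting", "count"),
    "junction_count": ("sprouting", "count"),
}


def circumference(ring: RingExplant) -> float:
    """Outer circumference of the explant in um."""
    return ring.circumference


def vessel_structure_pct(net: VesselNetwork) -> float:
    """Primary vessels as a percentage of all vessels (initial + branch)."""
    if net.is_empty:
        raise UndefinedParameterError("vessel structure undefined for empty network")
    n_init = len(net.initial_segments)
    return 100.0 * n_init / net.n_segments


def count_loops(net: VesselNetwork, merge_tol: float = DEFAULT_MERGE_TOL) -> int:
    """Closed circuits of three or more interconnected segments."""
    if net.is_empty:
        return 0
    jg = build_junction_graph(net, merge_tol)
    return count_independent_loops(jg, min_segments=3)


def max_radial_outgrowth(net: VesselNetwork) -> float:
    """Greatest perpendicular distance from the ring edge to any vessel tip.

    Measured at a right angle from the outer edge of the ring, i.e. the
    shortest point-to-boundary distance of the farthest tip; branch tips
    count too.  This is bounded by (and usually below) the path length of
    the vessel, which may curve tangentially.
    """
    if net.is_empty:
        raise UndefinedParameterError("radial outgrowth undefined for empty network")
    d = net.ring.distance_to_boundary(net.tips())
    return float(np.max(d))


def max_initial_vessel_length(net: VesselNetwork) -> float:
    """Path length of the longest initial vessel, branches not included."""
    initials = net.initial_segments
    if not initials:
        raise UndefinedParameterError("no initial vessels")
    return max(s.length for s in initials)


def total_and_mean_vessel_length(net: VesselNetwork) -> tuple[float, float]:
    """Sum of all segment lengths, and that sum over the segment count."""
    if net.is_empty:
        raise UndefinedParameterError("vessel length undefined for empty network")
    lengths = [s.length for s in net.segments.values()]
    total = float(sum(lengths))
    return total, total / len(lengths)


def _mean_initial_length(net: VesselNetwork) -> float:
    initials = net.initial_segments
    if not initials:
        raise UndefinedParameterError("no initial vessels")
    return float(np.mean([s.length for s in initials]))


def growth_speeds(
    obs_early: ExplantObservation, obs_late: ExplantObservation
) -> dict[str, float]:
    """Growth speed of the mean and maximum initial vessel length.

    Uses the exact elapsed time between the two microscopy sessions; returns
    per-hour and per-day values.  Speeds may be negative if regression was
    observed.
    """
    if (obs_early.donor, obs_early.ring_id) != (obs_late.donor, obs_late.ring_id):
        raise ValueError("growth speeds compare the same ring at two timepoints")
    dt_h = obs_late.imaging_time_h - obs_early.imaging_time_h
    if dt_h <= 0:
        raise ValueError("late observation must come after early observation")
    if obs_early.network is None or obs_late.network is None:
        raise UndefinedParameterError("both observations need a network")
    mean_rate = (
        _mean_initial_length(obs_late.network) - _mean_initial_length(obs_early.network)
    ) / dt_h
    max_rate = (
        max_initial_vessel_length(obs_late.network)
        - max_initial_vessel_length(obs_early.network)
    ) / dt_h
    return {
        "mean_um_per_h": mean_rate,
        "mean_um_per_day": mean_rate * 24.0,
        "max_um_per_h": max_rate,
        "max_um_per_day": max_rate * 24.0,
    }


def vessel_count_and_density(net: VesselNetwork) -> tuple[int, float]:
    """Number of initial vessels, and that count per mm of ring circumference."""
    circ_mm = net.ring.circumference / 1000.0
    if circ_mm <= 0:
        raise InvalidGeometryError("ring circumference must be positive")
    count = len(net.initial_segments)
    return count, count / circ_mm


def branch_statistics(
    net: VesselNetwork, bin_width: float = 50.0
) -> tuple[int, float, tuple[np.ndarray, np.ndarray]]:
    """Branch number, mean branch length, and a relative-frequency histogram.

    Returns ``(n_branches, mean_length, (frequencies, bin_edges))`` with the
    histogram normalised so the frequencies sum to 1 when branches exist.
    """
    lengths = np.array([s.length for s in net.branch_segments])
    n = len(lengths)
    if n == 0:
        return 0, float("nan"), (np.array([]), np.array([0.0]))
    top = math.ceil(float(lengths.max()) / bin_width) * bin_width
    edges = np.arange(0.0, top + bin_width, bin_width)
    counts, edges = np.histogram(lengths, bins=edges)
    return n, float(lengths.mean()), (counts / n, edges)


def junction_counts(
    net: VesselNetwork, merge_tol: float = DEFAULT_MERGE_TOL
) -> tuple[int, float]:
    """Number of junction nodes, and junctions per initial vessel.

    A junction is a distinct attachment node where at least one branch
    originates (from an initial vessel or from another branch); attachment
    points closer than ``merge_tol`` um are one junction.
    """
    if net.is_empty:
        return 0, float("nan")
    jg = build_junction_graph(net, merge_tol)
    n_j = len(jg.junction_nodes)
    n_init = len(net.initial_segments)
    if n_init == 0:
        if n_j > 0:
            raise InconsistentNetworkError("junctions present without initial vessels")
        return 0, float("nan")
    return n_j, n_j / n_init


def roi_extrapolate_endpoints(counted: float, sector_angle_deg: float) -> float:
    """Scale endpoints counted in a circular sector ROI to the whole ring."""
    if not 0 < sector_angle_deg <= 360:
        raise ValueError("sector angle must be in (0, 360] degrees")
    return counted * 360.0 / sector_angle_deg


def vessel_area(
    r_max_um: float,
    sector_angle_deg: float,
    mode: str = "sector",
    r_ring_um: float | None = None,
) -> float:
    """Vessel area of a circular-sector ROI, in mm^2.

    ``sector`` mode treats the outgrowth as a sector of radius ``r_max``
    centred on the ring; ``annulus_sector`` measures the sector of the
    annulus between the ring edge and the ring edge plus ``r_max`` and needs
    ``r_ring_um``.
    """
    if r_max_um <= 0:
        raise ValueError("maximum outgrowth radius must be positive")
    if not 0 < sector_angle_deg <= 360:
        raise ValueError("sector angle must be in (0, 360] degrees")
    theta = math.radians(sector_angle_deg)
    if mode == "sector":
        area_um2 = 0.5 * theta * r_max_um**2
    elif mode == "annulus_sector":
        if r_ring_um is None:
            raise ValueError("annulus_sector mode requires the ring radius")
        area_um2 = 0.5 * theta * ((r_ring_um + r_max_um) ** 2 - r_ring_um**2)
    else:
        raise ValueError(f"unknown vessel-area mode {mode!r}")
    return area_um2 / 1e6


def quantify(
    obs: ExplantObservation,
    merge_tol: float = DEFAULT_MERGE_TOL,
    include_auxiliary: bool = False,
) -> list[ParameterRecord]:
    """All per-observation parameters of one ring as tidy records.

    Emits the twelve-parameter record set.  Non-migrated explants contribute
    migration=0 and zero counts, but *missing* (NaN) length metrics.  Growth
    speeds need two timepoints and are added at the table level (see
    :func:`angioring.tables.quantify_experiment`).
    """

    def rec(parameter: str, value: float) -> ParameterRecord:
        reg = {**PARAMETER_REGISTRY, **AUXILIARY_PARAMETERS}
        cat, units = reg[parameter]
        return ParameterRecord(
            donor=obs.donor,
            group=obs.group,
            ring_id=obs.ring_id,
            day=obs.day,
            imaging_time_h=obs.imaging_time_h,
            parameter=parameter,
            category=cat,
            value=float(value),
            units=units,
        )

    net = obs.network
    nan = float("nan")
    out = [rec("migration", 1.0 if obs.migrated else 0.0)]
    if net is not None:
        out.append(rec("circumference", net.ring.circumference))
    else:
        out.append(rec("circumference", nan))

    if net is None or net.is_empty:
        out += [
            rec("vessel_structure", nan),
            rec("loop_count", 0.0),
            rec("max_radial_outgrowth", nan),
            rec("max_initial_vessel_length", nan),
            rec("total_vessel_length", nan),
            rec("mean_vessel_length", nan),
            rec("vessel_density", 0.0 if net is not None else nan),
            rec("branch_count", 0.0),
            rec("mean_branch_length", nan),
            rec("junctions_per_vessel", nan),
        ]
        if include_auxiliary:
            out += [rec("vessel_count", 0.0), rec("junction_count", 0.0)]
        return out

    total, mean = total_and_mean_vessel_length(net)
    n_vessels, density = vessel_count_and_density(net)
    n_branches, mean_branch, _ = branch_statistics(net)
    jg = build_junction_graph(net, merge_tol)  # shared by loops and junctions
    n_junctions = len(jg.junction_nodes)
    per_vessel = n_junctions / n_vessels if n_vessels else float("nan")
    out += [
        rec("vessel_structure", vessel_structure_pct(net)),
        rec("loop_count", count_independent_loops(jg, min_segments=3)),
        rec("max_radial_outgrowth", max_radial_outgrowth(net)),
        rec("max_initial_vessel_length", max_initial_vessel_length(net)),
        rec("total_vessel_length", total),
        rec("mean_vessel_length", mean),
        rec("vessel_density", density),
        rec("branch_count", n_branches),
        rec("mean_branch_length", mean_branch),
        rec("junctions_per_vessel", per_vessel),
    ]
    if include_auxiliary:
        out += [rec("vessel_count", n_vessels), rec("junction_count", n_junctions)]
    return out
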