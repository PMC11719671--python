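"""Stochastic outgrowth simulator for aortic ring explants.

The generator is phenomenological: it emulates the observable kinetics of
explant outgrowth — primary vessels sprouting from the ring from day 1
onwards, decelerating elongation, hierarchical branching that drives the
primary-vessel fraction down over time, and tip anastomosis that closes
loops — without modelling endothelial biology.

Key modelling choices (all rates in the units stated on ``GrowthParams``):

* Initial vessels are seeded by a Poisson process spread uniformly over the
  assay horizon, so the vessel count (and density) rises over the
  observation days; ``seed_density`` is the *expected final-day* density.
* Tip elongation decays exponentially with assay time
  (``elongation * exp(-elongation_decay * t)``), reproducing the observed
  slow-down of growth between day 4 and day 7.
* Branch events form a Poisson process with intensity
  ``branching_rate * total vessel length``; branching starts only after
  ``branch_onset_day`` (the initial sprouting phase produces primary
  vessels only, so day-1 snapshots are 100% primary).
* A treatment multiplier scales elongation and branching rate.

Each ring has its own counter-based random substream derived from
(seed, group, donor, ring), so adding rings or groups never perturbs the
trajectories of existing ones, and identical seeds give identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .model import ExplantObservation, RingExplant, VesselNetwork, VesselSegment

__all__ = [
    "GrowthParams",
    "SimulationConfig",
    "simulate_ring",
    "simulate_trajectory",
    "simulate_experiment",
    "render_mask",
    "roundtrip_growth_params",
    "generate_well_separated",
]

def _group_code(name: str) -> int:
    # deterministic: hash on bytes, independent of PYTHONHASHSEED
    h = 0
    for b in name.encode():
        h = (h * 131 + b) % (2**31 - 1)
    return h


@dataclass
class GrowthParams:
    """Rates governing one condition's outgrowth.

    Defaults emulate the control condition of a day-14 chick aorta explant in
    matrigel: ~20-25 initial vessels on a ~3.4 mm ring by day 7, maximum
    initial lengths around 700 um, and on the order of 50-100 branches.
    """

    seed_density: float = 7.0  # expected initial vessels per mm ring, final day
    elongation: float = 160.0  # tip speed at t=0, um/day
    elongation_decay: float = 0.15  # 1/day; growth slows as the assay matures
    direction_jitter: float = 20.0  # degrees per sqrt(day), tip direction noise
    branching_rate: float = 1.5  # branch events per mm vessel per day
    branch_onset_day: float = 1.0  # no branching during initial sprouting
    branch_angle_deg: tuple[float, float] = (30.0, 90.0)  # |angle| from parent
    anastomosis_prob: float = 0.25  # per step, tip within capture radius
    capture_radius: float = 20.0  # um
    treatment_multiplier: float = 1.0  # scales elongation and branching_rate
    seed_window_days: float | None = None  # None = spread over full horizon

    def __post_init__(self) -> None:
        for name in (
            "seed_density",
            "elongation",
            "elongation_decay",
            "direction_jitter",
            "branching_rate",
            "anastomosis_prob",
            "capture_radius",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.treatment_multiplier <= 0:
            raise ValueError("treatment_multiplier must be positive")

    def with_multiplier(self, m: float) -> "GrowthParams":
        return replace(self, treatment_multiplier=m)


@dataclass
class SimulationConfig:
    """One in-silico experiment: donors x rings x {control, treatment}."""

    days: tuple[int, ...] = (1, 4, 7)
    rings_per_group: int = 5
    donors: int = 3
    ring_radius: float = 540.0  # um; circumference ~3.39 mm as in the assay
    rng_seed: int = 0
    dt: float = 0.25  # day; growth substep
    treatment_group: str = "treatment"
    params_control: GrowthParams = field(default_factory=GrowthParams)
    params_treatment: GrowthParams = field(
        default_factory=lambda: GrowthParams(treatment_multiplier=1.5)
    )

    def __post_init__(self) -> None:
        if not self.days or any(d <= 0 for d in self.days):
            raise ValueError("observation days must be positive")
        self.days = tuple(sorted(int(d) for d in self.days))


class _Tip:
    __slots__ = ("seg_id", "direction", "active")

    def __init__(self, seg_id: str, direction: float):
        self.seg_id = seg_id
        self.direction = direction  # angle, radians
        self.active = True


def _ring_substream(config: SimulationConfig, group: str, donor: int, ring: int):
    return np.random.default_rng(
        [int(config.rng_seed), _group_code(group), int(donor), int(ring)]
    )


def simulate_trajectory(
    config: SimulationConfig, params: GrowthParams, rng: np.random.Generator
) -> dict[int, VesselNetwork]:
    """Grow one ring and snapshot the network at each observation day.

    Later-day networks contain the earlier-day networks as sub-geometries
    (monotone growth): segments only ever gain points.
    """
    ring = RingExplant(center=(0.0, 0.0), radius=config.ring_radius)
    horizon = float(max(config.days))
    dt = config.dt
    mult = params.treatment_multiplier

    # --- seeding plan ---------------------------------------------------------
    circ_mm = ring.circumference / 1000.0
    n_seeds = rng.poisson(params.seed_density * circ_mm)
    window = (
        horizon if params.seed_window_days is None else float(params.seed_window_days)
    )
    seed_times = np.sort(rng.uniform(0.0, window, size=n_seeds)) if window > 0 else (
        np.zeros(n_seeds)
    )
    seed_angles = rng.uniform(0.0, 2.0 * math.pi, size=n_seeds)

    polylines: dict[str, list[np.ndarray]] = {}
    kinds: dict[str, str] = {}
    parents: dict[str, str | None] = {}
    generations: dict[str, int] = {}
    tips: list[_Tip] = []
    counter = 0

    def new_segment(
        start: np.ndarray, direction: float, kind: str, parent: str | None
    ) -> str:
        nonlocal counter
        sid = f"s{counter:04d}"
        counter += 1
        polylines[sid] = [np.asarray(start, dtype=float)]
        kinds[sid] = kind
        parents[sid] = parent
        generations[sid] = 0 if parent is None else generations[parent] + 1
        tips.append(_Tip(sid, direction))
        return sid

    def snapshot() -> VesselNetwork:
        net = VesselNetwork(ring=ring, segments={})
        # include only segments that have actually grown; drop dangling
        # parent links to not-yet-grown parents cannot occur (children spawn
        # on grown length), so a plain copy suffices
        for sid, pts in polylines.items():
            if len(pts) >= 2:
                net.segments[sid] = VesselSegment(
                    id=sid,
                    polyline=np.array(pts),
                    kind=kinds[sid],
                    parent_id=parents[sid],
                    generation=generations[sid],
                )
        net.validate()
        return net

    def seg_length(sid: str) -> float:
        pts = polylines[sid]
        if len(pts) < 2:
            return 0.0
        arr = np.array(pts)
        return float(np.sum(np.linalg.norm(np.diff(arr, axis=0), axis=1)))

    snapshots: dict[int, VesselNetwork] = {}
    day_marks = set(config.days)
    n_steps = int(round(horizon / dt))
    seeds_used = 0
    jitter_rad = math.radians(params.direction_jitter)
    amin, amax = params.branch_angle_deg

    t = 0.0
    if 0 in day_marks:  # not reachable (days positive) but kept for clarity
        snapshots[0] = snapshot()
    for _ in range(n_steps):
        t_next = t + dt
        # activate seeds scheduled in (t, t_next]
        while seeds_used < n_seeds and seed_times[seeds_used] <= t_next:
            ang = seed_angles[seeds_used]
            start = ring.boundary_point(ang)
            direction = ang + rng.normal(0.0, 0.5 * jitter_rad)
            new_segment(start, direction, "initial", None)
            seeds_used += 1

        rate = params.elongation * mult * math.exp(-params.elongation_decay * t)
        step_len = rate * dt

        # elongate tips
        for tip in tips:
            if not tip.active or step_len <= 0:
                continue
            tip.direction += rng.normal(0.0, jitter_rad * math.sqrt(dt))
            pts = polylines[tip.seg_id]
            pos = pts[-1] + step_len * np.array(
                [math.cos(tip.direction), math.sin(tip.direction)]
            )
            # do not grow back into the explant: deflect outward
            r = np.linalg.norm(pos - np.asarray(ring.center))
            if r < config.ring_radius:
                out = (pts[-1] - np.asarray(ring.center)) / max(
                    np.linalg.norm(pts[-1] - np.asarray(ring.center)), 1e-9
                )
                tip.direction = math.atan2(out[1], out[0])
                pos = pts[-1] + step_len * out
            pts.append(pos)

        # branching along the existing network
        if t >= params.branch_onset_day and params.branching_rate > 0:
            lengths = {sid: seg_length(sid) for sid in polylines}
            total_mm = sum(lengths.values()) / 1000.0
            lam = params.branching_rate * mult * total_mm * dt
            for _ in range(rng.poisson(lam)):
                sids = list(lengths)
                weights = np.array([lengths[s] for s in sids])
                if weights.sum() <= 0:
                    break
                sid = sids[rng.choice(len(sids), p=weights / weights.sum())]
                pts = np.array(polylines[sid])
                d = np.linalg.norm(np.diff(pts, axis=0), axis=1)
                cum = np.concatenate([[0.0], np.cumsum(d)])
                s_at = rng.uniform(0.0, cum[-1])
                i = int(np.searchsorted(cum, s_at, side="right") - 1)
                i = min(i, len(pts) - 2)
                frac = (s_at - cum[i]) / max(d[i], 1e-9)
                attach = pts[i] + frac * (pts[i + 1] - pts[i])
                parent_dir = math.atan2(*(pts[i + 1] - pts[i])[::-1])
                sign = rng.choice([-1.0, 1.0])
                dev = math.radians(rng.uniform(amin, amax))
                new_segment(attach, parent_dir + sign * dev, "branch", sid)

        # anastomosis: active tips close to another vessel may fuse
        if params.anastomosis_prob > 0:
            _try_anastomose(polylines, tips, params, rng)

        t = t_next
        day = int(round(t))
        if abs(t - day) < 1e-9 and day in day_marks:
            snapshots[day] = snapshot()

    for day in config.days:
        snapshots.setdefault(day, snapshot())
    return snapshots


def _try_anastomose(polylines, tips, params: GrowthParams, rng) -> None:
    from scipy.spatial import cKDTree

    from .graph import _project_to_polyline

    grown = {sid: pts for sid, pts in polylines.items() if len(pts) >= 2}
    if len(grown) < 2:
        return
    verts = np.vstack([np.array(p) for p in grown.values()])
    owner = np.concatenate([[sid] * len(p) for sid, p in grown.items()])
    tree = cKDTree(verts)
    max_step = params.elongation * params.treatment_multiplier  # vertex spacing bound
    for tip in tips:
        if not tip.active:
            continue
        pts = polylines[tip.seg_id]
        if len(pts) < 3:
            continue  # a fresh sprout next to its parent is not a loop
        p = pts[-1]
        idx = tree.query_ball_point(p, params.capture_radius + max_step)
        cand = {owner[i] for i in idx} - {tip.seg_id}
        if not cand:
            continue
        heading = np.array([math.cos(tip.direction), math.sin(tip.direction)])
        # fuse to the nearest point on a foreign vessel, forward of the tip
        best, bd = None, np.inf
        for sid in sorted(cand):
            d, _pos, foot = _project_to_polyline(p, np.array(grown[sid]))
            if d < bd and 0.0 < d <= params.capture_radius and (
                float(np.dot(foot - p, heading)) > 0.0
            ):
                best, bd = foot, d
        if best is None:
            continue
        if rng.random() >= params.anastomosis_prob:
            continue
        pts.append(best.copy())
        tip.active = False


def simulate_ring(
    config: SimulationConfig,
    group: str,
    day: int,
    rng: np.random.Generator | None = None,
    donor: int = 0,
    ring: int = 0,
) -> VesselNetwork:
    """Network of one ring of ``group`` at one observation day."""
    params = (
        config.params_control if group == "control" else config.params_treatment
    )
    if rng is None:
        rng = _ring_substream(config, group, donor, ring)
    return simulate_trajectory(config, params, rng)[day]


def simulate_experiment(
    config: SimulationConfig,
) -> tuple[list[ExplantObservation], "object"]:
    """All observations of a control-vs-treatment experiment.

    Returns the observation list and the exact ground-truth parameter table
    (computed from the true geometry, no rasterisation involved).
    """
    from .tables import quantify_experiment

    observations: list[ExplantObservation] = []
    for group in ("control", config.treatment_group):
        params = (
            config.params_control
            if group == "control"
            else config.params_treatment
        )
        for donor in range(config.donors):
            for ring_i in range(config.rings_per_group):
                rng = _ring_substream(config, group, donor, ring_i)
                nets = simulate_trajectory(config, params, rng)
                for day in config.days:
                    observations.append(
                        ExplantObservation(
                            donor=f"D{donor + 1}",
                            group=group,
                            ring_id=f"{group}-D{donor + 1}-R{ring_i + 1}",
                            day=day,
                            imaging_time_h=day * 24.0,
                            network=nets[day],
                        )
                    )
    table = quantify_experiment(observations)
    return observations, table


def render_mask(
    net: VesselNetwork,
    pixel_size: float = 2.0,
    vessel_width_px: int = 3,
    margin_um: float = 40.0,
) -> "MaskPair":
    """Rasterise a network into a vessel mask + ring mask pair.

    Vessels are drawn as ``vessel_width_px``-wide strokes along their
    polylines; the ring is a filled disk (circular rings) or polygon.  The
    output is suitable for a skeletonise round-trip.
    """
    from skimage.draw import disk as draw_disk, line as draw_line, polygon as draw_poly
    from skimage.morphology import dilation as _dilate, disk as disk_se

    from .skeletonize import MaskPair

    pts = [np.asarray(net.ring.center, dtype=float)]
    if net.ring.radius is not None:
        r = net.ring.radius
        c = np.asarray(net.ring.center)
        pts += [c + [r, r], c - [r, r]]
    else:
        pts += [net.ring.boundary.min(axis=0), net.ring.boundary.max(axis=0)]
    for seg in net.segments.values():
        pts.append(seg.polyline.min(axis=0))
        pts.append(seg.polyline.max(axis=0))
    pts = np.vstack(pts)
    lo = pts.min(axis=0) - margin_um
    hi = pts.max(axis=0) + margin_um
    width = int(np.ceil((hi[0] - lo[0]) / pixel_size)) + 1
    height = int(np.ceil((hi[1] - lo[1]) / pixel_size)) + 1

    def to_px(p):
        return (
            int(round((p[1] - lo[1]) / pixel_size)),  # row <- y
            int(round((p[0] - lo[0]) / pixel_size)),  # col <- x
        )

    ring_mask = np.zeros((height, width), dtype=bool)
    if net.ring.radius is not None:
        rr, cc = draw_disk(
            to_px(np.asarray(net.ring.center)),
            net.ring.radius / pixel_size,
            shape=ring_mask.shape,
        )
    else:
        b = net.ring.boundary
        rr, cc = draw_poly(
            (b[:, 1] - lo[1]) / pixel_size, (b[:, 0] - lo[0]) / pixel_size,
            shape=ring_mask.shape,
        )
    ring_mask[rr, cc] = True

    vessel = np.zeros((height, width), dtype=bool)
    for seg in net.segments.values():
        px_pts = [to_px(p) for p in seg.polyline]
        for (r0, c0), (r1, c1) in zip(px_pts[:-1], px_pts[1:]):
            rr, cc = draw_line(r0, c0, r1, c1)
            ok = (rr >= 0) & (rr < height) & (cc >= 0) & (cc < width)
            vessel[rr[ok], cc[ok]] = True
    if vessel_width_px > 1:
        vessel = _dilate(vessel, disk_se(vessel_width_px // 2))
    return MaskPair(vessel_mask=vessel, ring_mask=ring_mask, pixel_size=pixel_size)


def roundtrip_growth_params() -> GrowthParams:
    """Growth rates for raster round-trip studies.

    Sparser seeding and wider branch angles than the assay-emulating
    defaults, so that a useful fraction of simulated rings satisfies the
    well-separatedness conditions under which mask extraction is exact.
    """
    return GrowthParams(
        seed_density=1.8,
        elongation=160.0,
        elongation_decay=0.15,
        direction_jitter=9.0,
        branching_rate=1.0,
        branch_angle_deg=(40.0, 80.0),
        anastomosis_prob=0.4,
        capture_radius=25.0,
    )


def generate_well_separated(
    n: int, seed: int, day: int = 6, params: GrowthParams | None = None
) -> list[VesselNetwork]:
    """First ``n`` non-empty, well-separated simulated networks for a seed."""
    from .skeletonize import is_well_separated

    params = params or roundtrip_growth_params()
    config = SimulationConfig(
        rng_seed=seed,
        donors=1,
        rings_per_group=1,
        days=(day,),
        params_control=params,
        params_treatment=params,
    )
    out: list[VesselNetwork] = []
    ring_i = 0
    while len(out) < n:
        net = simulate_ring(config, "control", day, donor=0, ring=ring_i)
        ring_i += 1
        if not net.is_empty and is_well_separated(net):
            out.append(net)
        if ring_i > 1000 * n:
            raise RuntimeError("well-separated network yield unexpectedly low")
    return out
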