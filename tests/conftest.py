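import math

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from angioring import (
    ExplantObservation,
    RingExplant,
    VesselNetwork,
    VesselSegment,
)


@pytest.fixture
def ring500() -> RingExplant:
    return RingExplant(radius=500.0)


@pytest.fixture
def toy_net(ring500) -> VesselNetwork:
    """Three straight radial initials (200/300/500 um) and two branches
    (100/150 um) attached to the longest one at distinct points."""
    net = VesselNetwork(ring=ring500, segments={})
    for i, (ang, length) in enumerate([(0.0, 200.0), (2.0, 300.0), (4.0, 500.0)]):
        p0 = ring500.boundary_point(ang)
        d = np.array([math.cos(ang), math.sin(ang)])
        net.add(
            VesselSegment(
                id=f"i{i + 1}", polyline=np.array([p0, p0 + length * d]), kind="initial"
            )
        )
    p = net.segments["i3"].polyline
    perp = np.array([-math.sin(4.0), math.cos(4.0)])
    for j, (frac, length) in enumerate([(0.4, 100.0), (0.8, 150.0)]):
        a = p[0] + frac * (p[1] - p[0])
        net.add(
            VesselSegment(
                id=f"b{j + 1}",
                polyline=np.array([a, a + length * perp]),
                kind="branch",
                parent_id="i3",
            )
        )
    return net


@pytest.fixture
def triangle_net(ring500) -> VesselNetwork:
    """One initial whose two branches fuse tip-to-tip through a closing
    branch: a single loop of three interconnected branches."""
    net = VesselNetwork(ring=ring500, segments={})
    ang = 0.3
    rad = np.array([math.cos(ang), math.sin(ang)])
    perp = np.array([-math.sin(ang), math.cos(ang)])
    p0 = ring500.boundary_point(ang)
    tip = p0 + 300.0 * rad
    net.add(VesselSegment(id="i1", polyline=np.array([p0, tip]), kind="initial"))
    b1e = tip + 120.0 * rad + 90.0 * perp
    b2e = tip + 120.0 * rad - 90.0 * perp
    net.add(
        VesselSegment(
            id="b1", polyline=np.array([tip, b1e]), kind="branch", parent_id="i1"
        )
    )
    net.add(
        VesselSegment(
            id="b2", polyline=np.array([tip, b2e]), kind="branch", parent_id="i1"
        )
    )
    net.add(
        VesselSegment(
            id="b3", polyline=np.array([b1e, b2e]), kind="branch", parent_id="b1"
        )
    )
    return net


def make_observation(net, donor="D1", group="treatment", ring_id="R1", day=7):
    return ExplantObservation(
        donor=donor,
        group=group,
        ring_id=ring_id,
        day=day,
        imaging_time_h=day * 24.0,
        network=net,
    )


@pytest.fixture
def toy_obs(toy_net):
    return make_observation(toy_net)
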