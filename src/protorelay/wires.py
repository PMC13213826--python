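"""Hydrogen-bond graph construction and water-wire detection.

A hydrogen bond requires a donor-acceptor heavy-atom distance of at most
3.5 Angstrom and a donor-hydrogen-acceptor angle (measured at the hydrogen)
of at least 150 degrees; both boundaries are inclusive.  Atoms considered
are the heteroatoms of the catalytic imidic-acid fragment and water
oxygens/hydrogens.  A water wire is a simple directed path

    OD --H*--> w1 --> ... --> wk --> ND        (1 <= k <= 3)

in the hydrogen-bond digraph, where each edge points along the prospective
proton-donation direction, so every intermediate water accepts from its
predecessor and donates to its successor (the alternating donor/acceptor
roles of a Grotthuss relay).  A frame is catalytically competent when at
least one wire exists; when wires of several orders coexist the frame is
labelled with the minimal order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io_core import (
    ROLE_WATER_O,
    Frame,
    Topology,
    TopologyError,
    Trajectory,
    mic_displacement,
)

__all__ = [
    "HBond",
    "WaterWire",
    "WireStats",
    "find_hbonds",
    "find_wires",
    "competent_stats",
    "DIST_CUTOFF",
    "ANGLE_CUTOFF",
]

DIST_CUTOFF = 3.5  # Angstrom, donor-acceptor heavy-atom distance
ANGLE_CUTOFF = 150.0  # degrees, donor-hydrogen-acceptor angle


@dataclass(frozen=True)
class HBond:
    donor: int
    hydrogen: int
    acceptor: int
    distance: float
    angle: float


@dataclass(frozen=True)
class WaterWire:
    """Ordered water-oxygen indices plus the constituent hydrogen bonds."""

    waters: tuple[int, ...]
    bonds: tuple[HBond, ...]

    @property
    def order(self) -> int:
        return len(self.waters)


@dataclass
class WireStats:
    """Competent-configuration statistics over replica trajectories."""

    per_replica_percent: list[float]
    percent_mean: float
    percent_sd: float
    order_breakdown: dict[int, float]  # % of competent frames per minimal order
    frame_orders: list[list[int | None]] = field(repr=False, default_factory=list)


def _dha_angle(frame: Frame, donor: int, hydrogen: int, acceptor: int) -> float:
    v1 = mic_displacement(frame.coords[donor] - frame.coords[hydrogen], frame.box)
    v2 = mic_displacement(frame.coords[acceptor] - frame.coords[hydrogen], frame.box)
    c = float(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
    return math.degrees(math.acos(max(-1.0, min(1.0, c))))


def find_hbonds(
    frame: Frame,
    topology: Topology,
    dist_cutoff: float = DIST_CUTOFF,
    angle_cutoff: float = ANGLE_CUTOFF,
) -> list[HBond]:
    """All hydrogen bonds among fragment heteroatoms and waters.

    Every (donor heavy, hydrogen) pair is tested against every candidate
    acceptor, so both orientations of a water pair are evaluated
    independently.
    """
    if topology.fragment is None:
        raise TopologyError("catalytic fragment not annotated")
    frag = topology.fragment
    hetero = {frag["OD"], frag["ND"]}
    water_o = set(int(i) for i in topology.water_oxygens)
    acceptors = sorted(hetero | water_o)

    donors: list[tuple[int, int]] = []
    for h, heavy in topology.h_to_heavy.items():
        if heavy in hetero or heavy in water_o:
            donors.append((heavy, h))
    donors.sort()

    acc_coords = frame.coords[acceptors]
    bonds: list[HBond] = []
    for heavy, h in donors:
        d = mic_displacement(acc_coords - frame.coords[heavy], frame.box)
        dist = np.linalg.norm(d, axis=1)
        for a_idx, r in zip(acceptors, dist):
            if a_idx == heavy or r > dist_cutoff:
                continue
            ang = _dha_angle(frame, heavy, h, a_idx)
            if ang >= angle_cutoff:
                bonds.append(HBond(heavy, h, a_idx, float(r), ang))
    return bonds


def _edges(bonds: list[HBond]) -> dict[int, list[HBond]]:
    out: dict[int, list[HBond]] = {}
    for b in bonds:
        out.setdefault(b.donor, []).append(b)
    return out


def find_wires(
    frame: Frame,
    topology: Topology,
    max_waters: int = 3,
    dist_cutoff: float = DIST_CUTOFF,
    angle_cutoff: float = ANGLE_CUTOFF,
    source: str = "OD",
    target: str = "ND",
    directional: bool = True,
) -> list[WaterWire]:
    """Every simple donation-directed path source -> waters -> target.

    With ``directional=False`` the hydrogen-bond graph is treated as
    undirected ("both heteroatoms engaged" reading of competence): a path is
    reported when the heteroatoms are bridged by hydrogen bonds through up
    to ``max_waters`` waters regardless of donation direction.
    """
    if topology.fragment is None:
        raise TopologyError("catalytic fragment not annotated")
    frag = topology.fragment
    src, tgt = frag[source], frag[target]
    water_o = set(int(i) for i in topology.water_oxygens)
    bonds = find_hbonds(frame, topology, dist_cutoff, angle_cutoff)

    adjacency: dict[int, list[HBond]] = {}
    if directional:
        adjacency = _edges(bonds)
    else:
        for b in bonds:
            adjacency.setdefault(b.donor, []).append(b)
            rev = HBond(b.acceptor, b.hydrogen, b.donor, b.distance, b.angle)
            adjacency.setdefault(b.acceptor, []).append(rev)

    wires: list[WaterWire] = []

    def extend(node: int, path: list[int], bond_path: list[HBond]):
        for b in adjacency.get(node, ()):  # depth-first over donation edges
            nxt = b.acceptor
            if nxt == tgt:
                if path:  # at least one bridging water
                    wires.append(WaterWire(tuple(path), tuple(bond_path + [b])))
                continue
            if nxt in water_o and nxt not in path and len(path) < max_waters:
                extend(nxt, path + [nxt], bond_path + [b])

    extend(src, [], [])
    # deterministic order: by order, then by water indices
    wires.sort(key=lambda w: (w.order, w.waters))
    return wires


def minimal_wire_order(wires: list[WaterWire]) -> int | None:
    return min((w.order for w in wires), default=None)


def competent_stats(
    trajs: list[Trajectory],
    topology: Topology | None = None,
    max_waters: int = 3,
    dist_cutoff: float = DIST_CUTOFF,
    angle_cutoff: float = ANGLE_CUTOFF,
    directional: bool = True,
) -> WireStats:
    """Percent of competent frames (mean +/- SD across replicas).

    A frame is competent when at least one wire exists; the order breakdown
    pools competent frames over all replicas and uses each frame's minimal
    wire order.  The SD is the sample standard deviation (n-1) and is 0.0
    for a single replica.
    """
    if not trajs:
        raise ValueError("at least one replica trajectory is required")
    per_replica: list[float] = []
    frame_orders: list[list[int | None]] = []
    for traj in trajs:
        topo = topology if topology is not None else traj.topology
        orders: list[int | None] = []
        for frame in traj:
            wires = find_wires(
                frame,
                topo,
                max_waters=max_waters,
                dist_cutoff=dist_cutoff,
                angle_cutoff=angle_cutoff,
                directional=directional,
            )
            orders.append(minimal_wire_order(wires))
        frame_orders.append(orders)
        n_comp = sum(o is not None for o in orders)
        per_replica.append(100.0 * n_comp / len(orders) if orders else 0.0)

    mean = float(np.mean(per_replica))
    sd = float(np.std(per_replica, ddof=1)) if len(per_replica) > 1 else 0.0
    pooled = [o for orders in frame_orders for o in orders if o is not None]
    breakdown: dict[int, float] = {}
    if pooled:
        for k in range(1, max_waters + 1):
            breakdown[k] = 100.0 * sum(o == k for o in pooled) / len(pooled)
    return WireStats(per_replica, mean, sd, breakdown, frame_orders)
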