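"""Shared fixtures and independent oracles for the test suite.

The wire oracle here is deliberately written from scratch (plain nested
loops, its own distance/angle arithmetic) so that graph-search results can
be checked against an implementation that shares no code with the package.
"""

from __future__ import annotations

import math
from itertools import permutations

import numpy as np
import pytest

from protorelay.io_core import Topology, Frame
from protorelay.synthetic import FixtureSpec, make_fixture


def oracle_wires(
    frame: Frame,
    topology: Topology,
    max_waters: int = 3,
    dist_cutoff: float = 3.5,
    angle_cutoff: float = 150.0,
    source: str = "OD",
    target: str = "ND",
) -> set[tuple[int, ...]]:
    """Exhaustive search over every ordered water subset of size <= 3."""
    coords = frame.coords
    frag = topology.fragment
    waters = [int(i) for i in np.flatnonzero(topology.roles == "water_oxygen")]
    hydrogens_of: dict[int, list[int]] = {}
    for h, heavy in topology.h_to_heavy.items():
        hydrogens_of.setdefault(heavy, []).append(h)

    def hbonded(donor: int, acceptor: int) -> bool:
        dx = coords[acceptor] - coords[donor]
        if math.sqrt(float(dx @ dx)) > dist_cutoff:
            return False
        for h in hydrogens_of.get(donor, ()):
            v1 = coords[donor] - coords[h]
            v2 = coords[acceptor] - coords[h]
            cosang = float(v1 @ v2) / (
                math.sqrt(float(v1 @ v1)) * math.sqrt(float(v2 @ v2))
            )
            ang = math.degrees(math.acos(min(1.0, max(-1.0, cosang))))
            if ang >= angle_cutoff:
                return True
        return False

    src, tgt = frag[source], frag[target]
    found = set()
    for k in range(1, max_waters + 1):
        for combo in permutations(waters, k):
            chain = (src, *combo, tgt)
            if all(hbonded(a, b) for a, b in zip(chain[:-1], chain[1:])):
                found.add(tuple(combo))
    return found


def random_water_frame(
    n_waters: int, seed: int, box_half: float = 4.5
) -> tuple[Frame, Topology]:
    """Fragment plus randomly placed/oriented waters near the active site."""
    rng = np.random.default_rng(seed)
    frame, topo, _ = make_fixture(FixtureSpec(0, 0, 0.0, seed), verify=False)
    coords = [frame.coords[:5]]
    names = list(topo.atom_names[:5])
    resnames = list(topo.res_names[:5])
    resids = list(topo.res_ids[:5])
    elements = list(frame.elements[:5])
    for w in range(n_waters):
        o = rng.uniform(-box_half, box_half, 3)
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        perp = np.cross(axis, rng.normal(size=3))
        perp /= np.linalg.norm(perp)
        half = math.radians(104.5 / 2)
        h1 = o + 0.96 * (math.cos(half) * axis + math.sin(half) * perp)
        h2 = o + 0.96 * (math.cos(half) * axis - math.sin(half) * perp)
        coords.append(np.stack([o, h1, h2]))
        names += ["O", "H1", "H2"]
        resnames += ["HOH"] * 3
        resids += [2 + w] * 3
        elements += ["O", "H", "H"]
    from protorelay.io_core import annotate_fragment, infer_roles

    elements = np.array(elements, dtype="U2")
    roles, h2h = infer_roles(names, resnames, np.array(resids), elements)
    topo = Topology(names, resnames, np.array(resids), roles, h2h)
    topo = annotate_fragment(topo, {"CG": 0, "OD": 1, "ND": 2, "HO": 3, "HN": 4})
    return Frame(np.vstack(coords), elements), topo


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    return Rotation.random(rng=rng).as_matrix()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def one_water_fixture():
    return make_fixture(FixtureSpec(n_waters=4, wire_order=1, sigma=0.0, seed=3))


@pytest.fixture(scope="session")
def two_water_fixture():
    return make_fixture(FixtureSpec(n_waters=6, wire_order=2, sigma=0.0, seed=5))
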