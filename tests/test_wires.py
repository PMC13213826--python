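"""Hydrogen-bond detection and water-wire graph search vs. enumeration."""

import math

import numpy as np
import pytest

from conftest import oracle_wires, random_water_frame
from protorelay.io_core import Frame, Topology, annotate_fragment, infer_roles, Trajectory
from protorelay.synthetic import FixtureSpec, make_fixture, make_trajectory
from protorelay.wires import competent_stats, find_hbonds, find_wires, minimal_wire_order


def _pair_frame(angle_deg: float, d_oo: float = 2.8):
    """Water donating to the fragment oxygen at a controlled D-H-A angle."""
    names = ["CG", "OD", "ND", "HO", "HN", "O", "H1", "H2"]
    res = ["IMA"] * 5 + ["HOH"] * 3
    ids = np.array([1] * 5 + [2] * 3)
    el = np.array(["C", "O", "N", "H", "H", "O", "H", "H"])
    nd = np.array([9.5, 1.2, 0])
    ow = np.array([0.0, 0, 0])
    h1 = np.array([0.96, 0.0, 0.0])
    # place the acceptor so the angle at H between H->donor and H->acceptor
    # is exactly angle_deg and |donor-acceptor| is exactly d_oo
    alpha = math.radians(angle_deg)
    ell = 0.96 * math.cos(alpha) + math.sqrt(d_oo**2 - (0.96 * math.sin(alpha)) ** 2)
    direction = np.array([-math.cos(alpha), math.sin(alpha), 0.0])  # from h1
    acceptor = h1 + ell * direction
    coords = np.array(
        [[20, 20, 20], acceptor, nd, acceptor + [0.7, 0.7, 0], nd + [0.5, 0.9, 0],
         ow, h1, ow + [-0.4, -0.85, 0]]
    )
    roles, h2h = infer_roles(names, res, ids, el)
    topo = Topology(names, res, ids, roles, h2h)
    topo = annotate_fragment(topo, {"CG": 0, "OD": 1, "ND": 2, "HO": 3, "HN": 4})
    return Frame(coords, el), topo


def _bonds_between(bonds, donor, acceptor):
    return [b for b in bonds if b.donor == donor and b.acceptor == acceptor]


def test_ideal_linear_hbond_detected():
    frame, topo = _pair_frame(180.0)
    assert len(_bonds_between(find_hbonds(frame, topo), 5, 1)) == 1


@pytest.mark.parametrize(
    "angle,d,expected",
    [
        (149.0, 2.8, 0),  # angle below threshold
        (150.1, 2.8, 1),  # just above the angle threshold
        (160.0, 3.49, 1),  # just below the distance threshold
        (160.0, 3.51, 0),  # distance above threshold
    ],
)
def test_hbond_threshold_behaviour(angle, d, expected):
    frame, topo = _pair_frame(angle, d_oo=d)
    assert len(_bonds_between(find_hbonds(frame, topo), 5, 1)) == expected


def test_hbond_boundaries_are_inclusive():
    """A bond exactly at the cutoffs is kept (<= distance, >= angle)."""
    frame, topo = _pair_frame(155.0, d_oo=3.2)
    (bond,) = _bonds_between(find_hbonds(frame, topo), 5, 1)
    # rerun with cutoffs set to the measured values: still detected
    at = find_hbonds(frame, topo, dist_cutoff=bond.distance, angle_cutoff=bond.angle)
    assert len(_bonds_between(at, 5, 1)) == 1
    # infinitesimally tighter cutoffs: gone
    tight_d = find_hbonds(frame, topo, dist_cutoff=np.nextafter(bond.distance, 0.0),
                          angle_cutoff=bond.angle)
    assert not _bonds_between(tight_d, 5, 1)
    tight_a = find_hbonds(frame, topo, dist_cutoff=bond.distance,
                          angle_cutoff=np.nextafter(bond.angle, 180.0))
    assert not _bonds_between(tight_a, 5, 1)


def test_random_frames_match_exhaustive_enumeration():
    """Graph search equals brute-force path enumeration on random frames."""
    for seed in range(40):
        n_waters = 3 + seed % 10
        frame, topo = random_water_frame(n_waters, seed=seed)
        got = {w.waters for w in find_wires(frame, topo)}
        assert got == oracle_wires(frame, topo), f"seed {seed}"


def test_fixture_wires_detected(one_water_fixture, two_water_fixture):
    for (frame, topo, gt) in (one_water_fixture, two_water_fixture):
        wires = find_wires(frame, topo)
        assert len(wires) == 1 and wires[0].order == gt
        # wire structure: k+1 bonds, first donated by OD via H*, last to ND
        w = wires[0]
        assert len(w.bonds) == w.order + 1
        assert w.bonds[0].donor == topo.fragment["OD"]
        assert w.bonds[0].hydrogen == topo.fragment["HO"]
        assert w.bonds[-1].acceptor == topo.fragment["ND"]


def test_no_wire_fixture_empty():
    frame, topo, _ = make_fixture(FixtureSpec(5, 0, 0.0, seed=13))
    assert find_wires(frame, topo) == []


def test_reversed_protonation_reverses_direction():
    frame, topo, _ = make_fixture(FixtureSpec(6, 2, 0.0, seed=5), protonation="amide")
    assert find_wires(frame, topo, source="OD", target="ND") == []
    rev = find_wires(frame, topo, source="ND", target="OD")
    assert len(rev) == 1 and rev[0].order == 2


def test_distant_water_never_changes_wires(two_water_fixture):
    frame, topo, _ = two_water_fixture
    before = {w.waters for w in find_wires(frame, topo)}
    # append one water > 6 A from both heteroatoms (and everything else)
    o = np.array([0.0, 0.0, 9.0])
    coords = np.vstack([frame.coords, o, o + [0.96, 0, 0], o + [-0.24, 0.93, 0]])
    el = np.concatenate([frame.elements, ["O", "H", "H"]])
    names = topo.atom_names + ["O", "H1", "H2"]
    res = topo.res_names + ["HOH"] * 3
    ids = np.concatenate([topo.res_ids, [topo.res_ids.max() + 1] * 3])
    roles, h2h = infer_roles(names, res, ids, np.array(el, dtype="U2"))
    topo2 = annotate_fragment(
        Topology(names, res, ids, roles, h2h),
        {"CG": 0, "OD": 1, "ND": 2, "HO": 3, "HN": 4},
    )
    after = {w.waters for w in find_wires(Frame(coords, np.array(el, dtype="U2")), topo2)}
    assert after == before


def test_relaxed_distance_cutoff_only_adds_wires():
    for seed in range(15):
        frame, topo = random_water_frame(6, seed=100 + seed)
        tight = {w.waters for w in find_wires(frame, topo, dist_cutoff=3.5)}
        loose = {w.waters for w in find_wires(frame, topo, dist_cutoff=4.0)}
        assert tight <= loose


def test_undirected_mode_is_superset():
    for seed in range(15):
        frame, topo = random_water_frame(6, seed=200 + seed)
        directed = {w.waters for w in find_wires(frame, topo)}
        undirected = {w.waters for w in find_wires(frame, topo, directional=False)}
        assert directed <= undirected


# ---------------------------------------------------------------------------
# competent-configuration statistics
# ---------------------------------------------------------------------------


def test_stats_all_and_none_competent():
    spec = FixtureSpec(5, 1, 0.03, seed=1)
    traj, _ = make_trajectory(1.0, 40, spec, seed=3)
    st = competent_stats([traj])
    assert st.percent_mean == 100.0 and st.percent_sd == 0.0
    assert st.order_breakdown[1] == 100.0
    traj0, _ = make_trajectory(0.0, 40, spec, seed=3)
    assert competent_stats([traj0]).percent_mean == 0.0


def test_stats_recover_generator_fraction():
    spec = FixtureSpec(6, 2, 0.05, seed=1)
    traj, labels = make_trajectory(0.3, 400, spec, seed=11)
    st = competent_stats([traj])
    # detector agrees with the generator labels frame by frame
    detected = [o is not None for o in st.frame_orders[0]]
    assert detected == list(labels)


def test_stats_across_replicas():
    spec = FixtureSpec(5, 1, 0.03, seed=1)
    trajs = [make_trajectory(0.5, 60, spec, seed=s)[0] for s in (1, 2, 3)]
    st = competent_stats(trajs)
    per = np.array(st.per_replica_percent)
    assert st.percent_mean == pytest.approx(per.mean())
    assert st.percent_sd == pytest.approx(per.std(ddof=1))
    assert sum(st.order_breakdown.values()) == pytest.approx(100.0)


def test_minimal_order_rule():
    """A frame holding wires of order 1 and 2 is counted once, as order 1."""
    from protorelay.wires import WaterWire

    assert minimal_wire_order([]) is None
    w1 = WaterWire((5,), ())
    w2 = WaterWire((8, 11), ())
    assert minimal_wire_order([w2, w1]) == 1
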