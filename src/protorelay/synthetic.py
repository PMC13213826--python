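"""Synthetic inputs: active-site fixtures, toy trajectories, surrogate landscapes.

Three generators cover everything the analysis pipeline consumes:

* :func:`make_fixture` builds an imidic-acid fragment R-C(=NH)OH plus water
  molecules in which **exactly** ``wire_order`` waters form one
  geometrically valid proton-relay wire from the hydroxyl oxygen to the
  imine nitrogen (donor-acceptor distances 2.8 Angstrom, donor-H-acceptor
  angles of 180 degrees before noise), while all remaining waters sit at
  least 6 Angstrom away.  The guarantee is confirmed at build time by an
  exhaustive enumeration over all ordered water subsets of size <= 3.
* :func:`make_trajectory` draws frames that are independently competent
  with probability ``p`` (Bernoulli labels returned), emulating the
  competent-configuration statistic of the study trajectories.
* :func:`make_surrogate` constructs an analytic two-basin landscape (two
  Gaussian wells, a Gaussian ridge and a steep confining wall) whose
  forward barrier from the imidic basin and whose quadrature basin
  free-energy difference are calibrated numerically to the requested
  values, standing in for the QM/MM tautomerization surface.

Same seed, same output — bit-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations

import numpy as np
from scipy import optimize

from .io_core import (
    Frame,
    Topology,
    annotate_fragment,
    infer_roles,
)

__all__ = [
    "FixtureSpec",
    "SurrogatePotential",
    "DoubleWell1D",
    "HarmonicWell",
    "InfeasibleSpecError",
    "make_fixture",
    "make_trajectory",
    "make_surrogate",
    "make_double_well",
    "KB_KCAL",
]

#: Boltzmann constant, kcal/mol/K.
KB_KCAL = 0.0019872041


class InfeasibleSpecError(ValueError):
    """The requested synthetic construction cannot satisfy its guarantees."""


# ---------------------------------------------------------------------------
# fixture geometry
# ---------------------------------------------------------------------------

_OH = 0.96  # covalent O-H bond length, Angstrom
_NH = 1.01  # covalent N-H bond length, Angstrom
_WIRE_DA = 2.8  # donor-acceptor distance along the wire, Angstrom
_DISTRACTOR_MIN = 6.0  # minimum distance of non-wire waters, Angstrom


@dataclass(frozen=True)
class FixtureSpec:
    """Specification of one active-site fixture.

    ``wire_order`` = 0 means no wire exists; 1-3 means exactly one wire of
    that many bridging waters.  ``sigma`` is an isotropic Gaussian
    coordinate noise (Angstrom) applied to every atom after construction.
    """

    n_waters: int
    wire_order: int
    sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.wire_order <= 3:
            raise ValueError("wire_order must be in 0..3")
        if self.wire_order > self.n_waters:
            raise ValueError("wire_order cannot exceed n_waters")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")


def _fragment_coords() -> np.ndarray:
    """CG, OD, ND of the imidic fragment in the xy-plane (Angstrom)."""
    half = math.radians(62.0)  # half the O-C-N angle
    cg = np.zeros(3)
    od = np.array([1.33 * math.cos(half), 1.33 * math.sin(half), 0.0])
    nd = np.array([1.28 * math.cos(half), -1.28 * math.sin(half), 0.0])
    return np.stack([cg, od, nd])


@lru_cache(maxsize=8)
def _wire_water_positions(k: int) -> tuple[tuple[float, float, float], ...]:
    """Water-oxygen positions of a k-water wire from OD to ND.

    Solved numerically: consecutive chain distances (OD, w1..wk, ND) equal
    2.8 Angstrom exactly, non-adjacent chain atoms stay >= 3.75 Angstrom
    apart and every water keeps >= 3.2 Angstrom from the fragment carbon.
    The one-water case is the most strained geometry (a water equidistant
    from both heteroatoms).
    """
    frag = _fragment_coords()
    cg, od, nd = frag
    if k == 0:
        return ()

    mid = 0.5 * (od + nd)
    out = mid - cg
    out /= np.linalg.norm(out)
    span = nd - od

    # arc-like initial guess fanning outward from the fragment
    guesses = []
    for i in range(1, k + 1):
        t = i / (k + 1)
        bulge = 1.4 * k * math.sin(math.pi * t)
        p = od + t * span + bulge * out
        p[2] += 0.7 * ((i % 2) * 2 - 1) if k == 3 else 0.0
        guesses.append(p)
    x0 = np.concatenate(guesses)

    def residuals(x):
        w = x.reshape(k, 3)
        chain = [od] + list(w) + [nd]
        res = []
        for a, b in zip(chain[:-1], chain[1:]):
            res.append(np.linalg.norm(a - b) - _WIRE_DA)
        for i in range(len(chain)):
            for j in range(i + 2, len(chain)):
                if i == 0 and j == len(chain) - 1:
                    continue  # OD-ND separation is fixed by the fragment
                d = np.linalg.norm(chain[i] - chain[j])
                res.append(5.0 * max(0.0, 3.75 - d))
        for wi in w:
            res.append(5.0 * max(0.0, 3.0 - np.linalg.norm(wi - cg)))
        return np.array(res)

    sol = optimize.least_squares(residuals, x0, xtol=1e-14, ftol=1e-14, gtol=1e-14)
    w = sol.x.reshape(k, 3)
    chain = [od] + list(w) + [nd]
    for a, b in zip(chain[:-1], chain[1:]):
        if abs(np.linalg.norm(a - b) - _WIRE_DA) > 1e-6:
            raise InfeasibleSpecError(f"could not solve {k}-water wire geometry")
    return tuple(tuple(float(c) for c in p) for p in w)


def _place_free_hydrogen(o: np.ndarray, prev: np.ndarray, nxt: np.ndarray) -> np.ndarray:
    """Second water hydrogen, pointing away from both chain neighbours."""
    u = (prev - o) / np.linalg.norm(prev - o)
    v = (nxt - o) / np.linalg.norm(nxt - o)
    d = -(u + v)
    n = np.linalg.norm(d)
    if n < 1e-8:  # neighbours exactly opposite: pick any perpendicular
        d = np.cross(u, [0.0, 0.0, 1.0])
        if np.linalg.norm(d) < 1e-8:
            d = np.cross(u, [0.0, 1.0, 0.0])
        n = np.linalg.norm(d)
    return o + _OH * d / n


def _random_water_orientation(o: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    perp = np.cross(axis, rng.normal(size=3))
    perp /= np.linalg.norm(perp)
    half = math.radians(104.5 / 2)
    h1 = o + _OH * (math.cos(half) * axis + math.sin(half) * perp)
    h2 = o + _OH * (math.cos(half) * axis - math.sin(half) * perp)
    return np.stack([h1, h2])


def _build_fixture_coords(
    spec: FixtureSpec, rng: np.random.Generator, protonation: str
) -> np.ndarray:
    """Noise-free atom coordinates: fragment (5 atoms) then waters (O,H,H)."""
    frag = _fragment_coords()
    cg, od, nd = frag
    k = spec.wire_order
    wire = [np.array(p) for p in _wire_water_positions(k)]

    if protonation == "imidic":
        src, tgt = od, nd
        chain = [src] + wire + [tgt]
    elif protonation == "amide":
        src, tgt = nd, od
        chain = [src] + wire[::-1] + [tgt]
    else:
        raise ValueError("protonation must be 'imidic' or 'amide'")

    # mobile proton H* on the source heteroatom, aimed along the wire
    if k >= 1:
        h_star = src + _OH * (chain[1] - src) / np.linalg.norm(chain[1] - src)
    else:
        away = src - 0.5 * (cg + (nd if protonation == "imidic" else od))
        h_star = src + _OH * away / np.linalg.norm(away)
    # imine/amide proton H_N stays on ND pointing away from the wire region
    back = nd - 0.6 * cg - 0.4 * od
    h_n = nd + _NH * back / np.linalg.norm(back)

    coords = [cg, od, nd, h_star, h_n]

    # wire waters: donating hydrogen exactly on the donor->acceptor segment
    water_atoms: dict[int, np.ndarray] = {}
    order = range(len(wire)) if protonation == "imidic" else range(len(wire) - 1, -1, -1)
    for pos_in_chain, wi in enumerate(order, start=1):
        o = chain[pos_in_chain]
        nxt = chain[pos_in_chain + 1]
        prev = chain[pos_in_chain - 1]
        h_donate = o + _OH * (nxt - o) / np.linalg.norm(nxt - o)
        h_free = _place_free_hydrogen(o, prev, nxt)
        water_atoms[wi] = np.stack([o, h_donate, h_free])
    for wi in range(len(wire)):
        coords.extend(water_atoms[wi])

    # distractor waters, >= 6 A from every fragment/wire atom
    core = np.array(coords)
    placed: list[np.ndarray] = []
    for _ in range(spec.n_waters - k):
        for _attempt in range(10_000):
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            o = cg + rng.uniform(_DISTRACTOR_MIN + 1.0, _DISTRACTOR_MIN + 6.0) * direction
            dmin = np.min(np.linalg.norm(core - o, axis=1))
            if placed:
                dmin = min(dmin, min(np.linalg.norm(p[0] - o) for p in placed))
            if dmin >= _DISTRACTOR_MIN:
                break
        else:
            raise InfeasibleSpecError("could not place distractor waters")
        hh = _random_water_orientation(o, rng)
        placed.append(np.vstack([o, hh]))
    for w in placed:
        coords.extend(w)
    return np.array(coords)


def _fixture_topology(n_waters: int, protonation: str) -> tuple[Topology, np.ndarray]:
    names = ["CG", "OD", "ND", "HO", "HN"]
    resnames = ["IMA"] * 5
    resids = [1] * 5
    elements = ["C", "O", "N", "H", "H"]
    for w in range(n_waters):
        names += ["O", "H1", "H2"]
        resnames += ["HOH"] * 3
        resids += [2 + w] * 3
        elements += ["O", "H", "H"]
    elements = np.array(elements, dtype="U2")
    roles, h_to_heavy = infer_roles(names, resnames, np.array(resids), elements)
    topo = Topology(names, resnames, np.array(resids), roles, h_to_heavy)
    topo = annotate_fragment(topo, {"CG": 0, "OD": 1, "ND": 2, "HO": 3, "HN": 4})
    if protonation == "amide":
        # the mobile proton sits on the nitrogen: swap donor/acceptor roles
        roles = topo.roles.copy()
        roles[1], roles[2] = "hb_acceptor_heavy", "hb_donor_heavy"
        h_to_heavy = dict(topo.h_to_heavy)
        h_to_heavy[3] = 2
        topo = Topology(
            topo.atom_names, topo.res_names, topo.res_ids, roles, h_to_heavy,
            fragment=topo.fragment,
        )
    return topo, elements


def enumerate_wires_bruteforce(
    frame: Frame,
    topology: Topology,
    max_waters: int = 3,
    dist_cutoff: float = 3.5,
    angle_cutoff: float = 150.0,
    source: str = "OD",
    target: str = "ND",
) -> set[tuple[int, ...]]:
    """Exhaustive wire search over all ordered water subsets of size <= 3.

    Plain nested-loop reference used to certify generator output (the test
    suite carries its own independent copy for cross-checking the graph
    search).  Returns the set of ordered water-oxygen index tuples.
    """
    frag = topology.fragment
    coords = frame.coords
    waters = [int(i) for i in topology.water_oxygens]

    def bonded(donor: int, acceptor: int) -> bool:
        if np.linalg.norm(coords[donor] - coords[acceptor]) > dist_cutoff:
            return False
        for h, heavy in topology.h_to_heavy.items():
            if heavy != donor:
                continue
            v1 = coords[donor] - coords[h]
            v2 = coords[acceptor] - coords[h]
            c = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
            if math.degrees(math.acos(max(-1.0, min(1.0, c)))) >= angle_cutoff:
                return True
        return False

    found = set()
    src, tgt = frag[source], frag[target]
    for k in range(1, max_waters + 1):
        for combo in permutations(waters, k):
            chain = [src, *combo, tgt]
            if all(bonded(a, b) for a, b in zip(chain[:-1], chain[1:])):
                found.add(tuple(combo))
    return found


def make_fixture(
    spec: FixtureSpec,
    protonation: str = "imidic",
    verify: bool = True,
) -> tuple[Frame, Topology, int]:
    """Build one fixture and return (frame, topology, ground-truth order)."""
    rng = np.random.default_rng(spec.seed)
    coords = _build_fixture_coords(spec, rng, protonation)
    if spec.sigma > 0:
        coords = coords + rng.normal(0.0, spec.sigma, size=coords.shape)
    topo, elements = _fixture_topology(spec.n_waters, protonation)
    frame = Frame(coords, elements)
    if verify:
        src, tgt = ("OD", "ND") if protonation == "imidic" else ("ND", "OD")
        found = enumerate_wires_bruteforce(frame, topo, source=src, target=tgt)
        k = spec.wire_order
        expected_orders = {k} if k >= 1 else set()
        if {len(w) for w in found} != expected_orders or len(found) > 1:
            raise InfeasibleSpecError(
                f"noise sigma={spec.sigma} voided the wire guarantee "
                f"(expected one wire of order {k}, found {sorted(found)})"
            )
    return frame, topo, spec.wire_order


def make_trajectory(
    p_competent: float,
    n_frames: int,
    spec: FixtureSpec,
    seed: int = 0,
) -> tuple["Trajectory", np.ndarray]:
    """Frames independently competent with probability ``p_competent``.

    Competent frames carry the wire defined by ``spec``; incompetent frames keep the same
    number of waters, all placed beyond 6 Angstrom.  Per-frame Boolean
    labels are returned alongside the trajectory.
    """
    from .io_core import Trajectory

    if not 0.0 <= p_competent <= 1.0:
        raise ValueError("p_competent must lie in [0, 1]")
    if p_competent > 0 and spec.wire_order < 1:
        raise ValueError("competent frames require wire_order >= 1")

    rng = np.random.default_rng(seed)
    base = FixtureSpec(spec.n_waters, spec.wire_order, 0.0, spec.seed)
    comp_frame, topo, _ = make_fixture(base, verify=True)
    incomp_spec = FixtureSpec(spec.n_waters, 0, 0.0, spec.seed + 1)
    incomp_frame, _, _ = make_fixture(incomp_spec, verify=True)

    labels = rng.random(n_frames) < p_competent
    frames = []
    for lab in labels:
        template = comp_frame.coords if lab else incomp_frame.coords
        noise = rng.normal(0.0, spec.sigma, size=template.shape) if spec.sigma > 0 else 0.0
        frames.append(Frame(template + noise, comp_frame.elements))
    return Trajectory(frames, topo), labels


# ---------------------------------------------------------------------------
# surrogate energy landscapes
# ---------------------------------------------------------------------------


class _Potential:
    """Common vectorised wrappers around the scalar energy/gradient."""

    dim: int

    def energy(self, x):
        x = np.atleast_2d(np.asarray(x, dtype=float))
        return np.array([self.energy_and_grad_scalar(*xi)[0] for xi in x])

    def grad(self, x):
        x = np.atleast_2d(np.asarray(x, dtype=float))
        return np.array([self.energy_and_grad_scalar(*xi)[1] for xi in x])


@dataclass
class SurrogatePotential(_Potential):
    """Analytic two-basin stand-in for the tautomerization surface.

    ``s1`` plays the role of the bond-rearrangement axis (imidic basin at
    negative ``s1``, amide basin at positive ``s1``); ``s2`` the
    proton-transfer axis.  Energies in kcal/mol.
    """

    a1: float  # imidic well depth
    a2: float  # amide well depth
    well_width: float = 0.5
    ridge_height: float = 3.0
    ridge_width: float = 0.35
    # wall close and stiff: regions irrelevant to the two-basin problem sit
    # above the sampling bias cap, so biased walkers never dwell there
    wall_height: float = 30.0
    wall_scale_1: float = 1.9
    wall_scale_2: float = 1.5
    dG: float = 0.0
    dG_barrier: float = 0.0
    temperature: float = 300.0
    minima: np.ndarray | None = None
    saddle: np.ndarray | None = None
    dim: int = 2

    def energy_and_grad_scalar(self, s1: float, s2: float):
        w2 = self.well_width * self.well_width
        g1 = math.exp(-((s1 + 1.0) ** 2 + s2 * s2) / (2.0 * w2))
        g2 = math.exp(-((s1 - 1.0) ** 2 + s2 * s2) / (2.0 * w2))
        r = math.exp(-(s1 * s1) / (2.0 * self.ridge_width**2))
        u1, u2 = s1 / self.wall_scale_1, s2 / self.wall_scale_2
        v = (
            -self.a1 * g1
            - self.a2 * g2
            + self.ridge_height * r
            + self.wall_height * (u1**8 + u2**8)
        )
        d1 = (
            self.a1 * g1 * (s1 + 1.0) / w2
            + self.a2 * g2 * (s1 - 1.0) / w2
            - self.ridge_height * r * s1 / self.ridge_width**2
            + self.wall_height * 8.0 * u1**7 / self.wall_scale_1
        )
        d2 = (
            self.a1 * g1 * s2 / w2
            + self.a2 * g2 * s2 / w2
            + self.wall_height * 8.0 * u2**7 / self.wall_scale_2
        )
        return v, (d1, d2)

    # -- analytic reference quantities -------------------------------------

    def energy_grid(self, s1, s2):
        g1 = np.exp(-((s1 + 1.0) ** 2 + s2**2) / (2 * self.well_width**2))
        g2 = np.exp(-((s1 - 1.0) ** 2 + s2**2) / (2 * self.well_width**2))
        r = np.exp(-(s1**2) / (2 * self.ridge_width**2))
        wall = self.wall_height * (
            (s1 / self.wall_scale_1) ** 8 + (s2 / self.wall_scale_2) ** 8
        )
        return -self.a1 * g1 - self.a2 * g2 + self.ridge_height * r + wall

    def locate_critical_points(self) -> tuple[np.ndarray, np.ndarray]:
        """(minima (2,2) sorted by s1, saddle (2,)) by local optimisation."""
        minima = []
        for x0 in ((-1.0, 0.0), (1.0, 0.0)):
            res = optimize.minimize(
                lambda x: self.energy_and_grad_scalar(*x)[0],
                x0,
                jac=lambda x: np.array(self.energy_and_grad_scalar(*x)[1]),
                method="BFGS",
                options={"gtol": 1e-12},
            )
            minima.append(res.x)
        minima = np.array(sorted(minima, key=lambda m: m[0]))
        # the surface is even in s2, so the saddle lies on s2 = 0
        res = optimize.minimize_scalar(
            lambda s: -self.energy_and_grad_scalar(s, 0.0)[0],
            bounds=(minima[0, 0] + 0.05, minima[1, 0] - 0.05),
            method="bounded",
            options={"xatol": 1e-12},
        )
        return minima, np.array([res.x, 0.0])

    def quadrature_dG(self, grid_half: float = 2.2, n: int = 241) -> float:
        """Exact basin free-energy difference G(amide) - G(imidic)."""
        kt = KB_KCAL * self.temperature
        s = np.linspace(-grid_half, grid_half, n)
        s1, s2 = np.meshgrid(s, s, indexing="ij")
        v = self.energy_grid(s1, s2)
        boltz = np.exp(-(v - v.min()) / kt)
        _, saddle = self.locate_critical_points()
        imid = boltz[s1 <= saddle[0]].sum()
        amide = boltz[s1 > saddle[0]].sum()
        return float(-kt * math.log(amide / imid))

    def barrier(self) -> float:
        """Forward barrier: energy at the saddle minus the imidic minimum."""
        minima, saddle = self.locate_critical_points()
        return float(
            self.energy_and_grad_scalar(*saddle)[0]
            - self.energy_and_grad_scalar(*minima[0])[0]
        )


def make_surrogate(
    dG: float,
    dG_barrier: float,
    temperature: float = 300.0,
) -> SurrogatePotential:
    """Calibrated two-basin landscape with the requested barrier and offset.

    ``dG`` is G(amide) - G(imidic) in kcal/mol (amide lower when negative);
    ``dG_barrier`` is the forward barrier from the imidic basin.  The two
    well depths are solved numerically so that the located saddle minus the
    imidic minimum equals ``dG_barrier`` and the quadrature basin
    free-energy difference equals ``dG``.
    """
    if dG_barrier <= max(0.0, dG):
        raise InfeasibleSpecError("dG_barrier must exceed max(0, dG)")

    def build(a):
        return SurrogatePotential(
            a1=a[0], a2=a[1], dG=dG, dG_barrier=dG_barrier, temperature=temperature
        )

    def residuals(a):
        pot = build(a)
        return [pot.barrier() - dG_barrier, pot.quadrature_dG() - dG]

    x0 = np.array([max(1.5, dG_barrier / 0.7), max(1.5, dG_barrier / 0.7 - dG)])
    sol = optimize.least_squares(
        residuals, x0, bounds=([0.5, 0.5], [80.0, 80.0]), xtol=1e-12, ftol=1e-12
    )
    res = residuals(sol.x)
    if max(abs(r) for r in res) > 1e-4:
        raise InfeasibleSpecError(
            f"could not calibrate surrogate for dG={dG}, barrier={dG_barrier}"
        )
    pot = build(sol.x)
    minima, saddle = pot.locate_critical_points()
    pot.minima, pot.saddle = minima, saddle

    # certify exactly two minima on a grid restricted to the bowl region
    s = np.linspace(-2.0, 2.0, 161)
    v = pot.energy_grid(*np.meshgrid(s, s, indexing="ij"))
    interior = v[1:-1, 1:-1]
    is_min = (
        (interior < v[:-2, 1:-1]) & (interior < v[2:, 1:-1])
        & (interior < v[1:-1, :-2]) & (interior < v[1:-1, 2:])
        & (interior < v[:-2, :-2]) & (interior < v[2:, 2:])
        & (interior < v[:-2, 2:]) & (interior < v[2:, :-2])
    )
    if int(is_min.sum()) != 2:
        raise InfeasibleSpecError("surrogate does not have exactly two minima")
    return pot


@dataclass
class DoubleWell1D(_Potential):
    """Symmetric quartic double well V = b (x^2 - 1)^2 + tilt * x / 2."""

    barrier: float
    tilt: float = 0.0
    dim: int = 1

    def energy_and_grad_scalar(self, x: float):
        q = x * x - 1.0
        return (
            self.barrier * q * q + 0.5 * self.tilt * x,
            (4.0 * self.barrier * q * x + 0.5 * self.tilt,),
        )


def make_double_well(barrier: float, tilt: float = 0.0) -> DoubleWell1D:
    if barrier <= 0:
        raise InfeasibleSpecError("barrier must be positive")
    return DoubleWell1D(barrier=barrier, tilt=tilt)


@dataclass
class HarmonicWell(_Potential):
    """Isotropic harmonic well V = k/2 |x|^2 (for sampling validation)."""

    k: float = 1.0
    dim: int = 1

    def energy_and_grad_scalar(self, *x):
        v = 0.5 * self.k * sum(xi * xi for xi in x)
        return v, tuple(self.k * xi for xi in x)
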