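"""Coordination-number collective variables.

The coordination number of a proton with a heteroatom is a rational
switching function of their distance,

    s(r) = (1 - (r/r0)^6) / (1 - (r/r0)^12)

which simplifies algebraically to 1/(1 + (r/r0)^6); the simplified form is
used everywhere because it removes the r = r0 singularity exactly and keeps
derivatives smooth.  The proton-transfer CV is the difference of summed
coordination numbers of the transferable protons with the imine nitrogen and
the hydroxyl oxygen of the catalytic fragment,

    CV = CN_N - CN_O ,

negative in the imidic state (H* on the oxygen) and positive in the amide
state.  The free-energy-surface axes are CV1 = d(C,N) - d(C,O) (Angstrom)
and CV2, the same coordination-number difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_core import Frame, Topology, TopologyError, mic_displacement

__all__ = [
    "SwitchingParams",
    "ProtonSet",
    "CVValues",
    "switch",
    "switch_grad",
    "cv_opes",
    "cv_opes_grad",
    "cv_axes",
    "protons_from_topology",
]


@dataclass(frozen=True)
class SwitchingParams:
    """Rational switching function parameters (r0 in Angstrom)."""

    r0: float = 1.1
    n_exp: int = 6
    m_exp: int = 12

    def __post_init__(self):
        if self.r0 <= 0:
            raise ValueError("r0 must be positive")
        if self.n_exp <= 0 or self.m_exp != 2 * self.n_exp:
            raise ValueError("exponents must be positive with m = 2n")


@dataclass(frozen=True)
class ProtonSet:
    """Indices of the transferable protons (H* plus water hydrogens).

    The imine proton H_N is never part of the set.  The canonical sizes are
    3 (one bridging water) and 5 (two bridging waters).
    """

    indices: tuple[int, ...]

    def __post_init__(self):
        if len(self.indices) == 0:
            raise ValueError("proton set must not be empty")
        if len(set(self.indices)) != len(self.indices):
            raise ValueError("duplicate proton indices")

    def __len__(self) -> int:
        return len(self.indices)


@dataclass(frozen=True)
class CVValues:
    cv_opes: float
    cv1: float
    cv2: float


def switch(r, params: SwitchingParams = SwitchingParams()):
    """Rational switching function, evaluated as 1/(1 + (r/r0)^n).

    Accepts scalars or arrays; value in (0, 1] with switch(0) = 1 and
    switch(r0) = 1/2 (the removable-singularity limit).
    """
    x = np.asarray(r, dtype=float) / params.r0
    out = 1.0 / (1.0 + x**params.n_exp)
    return float(out) if out.ndim == 0 else out


def switch_grad(r, params: SwitchingParams = SwitchingParams()):
    """d switch / d r (same shape as ``r``)."""
    x = np.asarray(r, dtype=float) / params.r0
    n = params.n_exp
    out = -(n / params.r0) * x ** (n - 1) / (1.0 + x**n) ** 2
    return float(out) if out.ndim == 0 else out


def _require_fragment(topology: Topology) -> dict[str, int]:
    if topology.fragment is None:
        raise TopologyError("catalytic fragment not annotated")
    return topology.fragment


def protons_from_topology(topology: Topology) -> ProtonSet:
    """Transferable protons: H* and all water hydrogens (H_N excluded)."""
    frag = _require_fragment(topology)
    idx = [frag["HO"]]
    idx += [int(i) for i in np.flatnonzero(topology.roles == "water_hydrogen")]
    idx = [i for i in idx if i != frag["HN"]]
    return ProtonSet(tuple(idx))


def _proton_distances(frame: Frame, heavy: int, protons: ProtonSet) -> np.ndarray:
    d = frame.coords[list(protons.indices)] - frame.coords[heavy]
    d = mic_displacement(d, frame.box)
    return np.linalg.norm(d, axis=1)


def cv_opes(
    frame: Frame,
    topology: Topology,
    protons: ProtonSet | None = None,
    params: SwitchingParams = SwitchingParams(),
) -> float:
    """CN_N - CN_O over the transferable protons (the biased OPES CV)."""
    frag = _require_fragment(topology)
    if protons is None:
        protons = protons_from_topology(topology)
    if frag["HN"] in protons.indices:
        raise ValueError("proton set must exclude the imine proton H_N")
    rn = _proton_distances(frame, frag["ND"], protons)
    ro = _proton_distances(frame, frag["OD"], protons)
    return float(np.sum(switch(rn, params)) - np.sum(switch(ro, params)))


def cv_opes_grad(
    frame: Frame,
    topology: Topology,
    protons: ProtonSet | None = None,
    params: SwitchingParams = SwitchingParams(),
) -> tuple[float, np.ndarray]:
    """CV value and its analytic gradient w.r.t. all atomic coordinates."""
    frag = _require_fragment(topology)
    if protons is None:
        protons = protons_from_topology(topology)
    grad = np.zeros_like(frame.coords)
    value = 0.0
    for heavy, sign in ((frag["ND"], +1.0), (frag["OD"], -1.0)):
        for h in protons.indices:
            d = mic_displacement(frame.coords[h] - frame.coords[heavy], frame.box)
            r = float(np.linalg.norm(d))
            value += sign * switch(r, params)
            g = sign * switch_grad(r, params) * d / r
            grad[h] += g
            grad[heavy] -= g
    return value, grad


def cv_axes(
    frame: Frame,
    topology: Topology,
    params: SwitchingParams = SwitchingParams(),
    include_imine_proton: bool = False,
) -> tuple[float, float]:
    """FES axes: CV1 = d(C,N) - d(C,O); CV2 = coordination-number difference.

    ``include_imine_proton`` adds H_N to the proton set for CV2, which maps
    the amide basin (two protons on the nitrogen) to CV2 near +1.5 instead
    of +0.5; the default excludes it, matching the biased OPES CV exactly.
    """
    frag = _require_fragment(topology)
    c, o, n = frag["CG"], frag["OD"], frag["ND"]
    d_cn = float(np.linalg.norm(mic_displacement(frame.coords[n] - frame.coords[c], frame.box)))
    d_co = float(np.linalg.norm(mic_displacement(frame.coords[o] - frame.coords[c], frame.box)))
    cv1 = d_cn - d_co
    protons = protons_from_topology(topology)
    if include_imine_proton:
        protons = ProtonSet(protons.indices + (frag["HN"],))
        rn = _proton_distances(frame, n, protons)
        ro = _proton_distances(frame, o, protons)
        cv2 = float(np.sum(switch(rn, params)) - np.sum(switch(ro, params)))
    else:
        cv2 = cv_opes(frame, topology, protons, params)
    return cv1, cv2
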