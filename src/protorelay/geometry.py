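"""Structural trajectory analytics: RMSD, RMSF and rolling-probe SASA.

RMSD uses least-squares optimal superposition (Kabsch, proper rotation
only).  RMSF is the per-atom root-mean-square deviation from the mean
position after superposing every frame onto a reference.  SASA is computed
with a Shrake-Rupley sphere-point algorithm (probe radius 1.4 Angstrom by
default, a water molecule) through biotite, with an explicit per-element
van der Waals radii table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

import biotite.structure as struc

from .io_core import Frame, Trajectory

__all__ = [
    "SasaParams",
    "RigidTransform",
    "DEFAULT_VDW_RADII",
    "DEFAULT_ACTIVE_SITE_RESIDUES",
    "superpose_rmsd",
    "apply_transform",
    "rmsf",
    "sasa",
]

#: Default van der Waals radii (Angstrom) used for SASA.
DEFAULT_VDW_RADII = {"C": 1.7, "N": 1.55, "O": 1.52, "S": 1.8, "H": 1.2, "P": 1.8}

#: Active-site residue names of the fucosyltransferase study system; the
#: matching atom indices must come from the topology at hand.
DEFAULT_ACTIVE_SITE_RESIDUES = (
    "MET46", "GLY47", "ARG48", "GLY50", "ASN51", "GLN52", "HIS55", "PHE204", "SER362",
)


class DegenerateSelectionError(ValueError):
    """Selection too small or collinear for a unique superposition."""


@dataclass(frozen=True)
class SasaParams:
    probe_radius: float = 1.4
    point_number: int = 960
    vdw_radii: dict = field(default_factory=lambda: dict(DEFAULT_VDW_RADII))

    def __post_init__(self):
        if self.probe_radius <= 0:
            raise ValueError("probe radius must be positive")
        if self.point_number < 92:
            raise ValueError("point count must be at least 92")


@dataclass(frozen=True)
class RigidTransform:
    """x -> rotation @ (x - mobile_center) + reference_center."""

    rotation: np.ndarray
    mobile_center: np.ndarray
    reference_center: np.ndarray


def apply_transform(coords: np.ndarray, t: RigidTransform) -> np.ndarray:
    return (coords - t.mobile_center) @ t.rotation.T + t.reference_center


def superpose_rmsd(
    mobile: Frame,
    reference: Frame,
    selection=None,
) -> tuple[float, RigidTransform]:
    """Optimal-superposition RMSD of ``mobile`` onto ``reference``.

    The same selection is used for fitting and measurement.  Returns the
    RMSD (Angstrom) and the fitted rigid transform (determinant +1).
    """
    sel = np.arange(mobile.n_atoms) if selection is None else np.asarray(selection)
    if len(sel) < 3:
        raise DegenerateSelectionError("selection must contain at least 3 atoms")
    p = mobile.coords[sel]
    q = reference.coords[sel]
    if p.shape != q.shape:
        raise ValueError("selections must have equal size")
    pc, qc = p.mean(axis=0), q.mean(axis=0)
    p0, q0 = p - pc, q - qc
    if np.linalg.matrix_rank(p0, tol=1e-8) < 2 or np.linalg.matrix_rank(q0, tol=1e-8) < 2:
        raise DegenerateSelectionError("selection is collinear")
    rot, _ = Rotation.align_vectors(q0, p0)
    rmat = rot.as_matrix()
    # recompute the residual from the aligned coordinates: the rssd returned
    # by align_vectors loses precision to cancellation near an exact match
    rmsd = float(np.sqrt(np.mean(np.sum((p0 @ rmat.T - q0) ** 2, axis=1))))
    return rmsd, RigidTransform(rmat, pc, qc)


def rmsf(
    traj: Trajectory,
    selection=None,
    reference: Frame | None = None,
    fit_selection=None,
) -> np.ndarray:
    """Per-atom RMSF after superposing every frame onto ``reference``.

    ``fit_selection`` (default: same as ``selection``) sets the atoms used
    for the superposition fit; the fluctuation is then measured on
    ``selection`` relative to the mean fitted position.
    """
    if len(traj) < 2:
        raise ValueError("RMSF needs at least two frames")
    sel = np.arange(traj.topology.n_atoms) if selection is None else np.asarray(selection)
    if len(sel) == 0:
        raise ValueError("empty selection")
    fit_sel = sel if fit_selection is None else np.asarray(fit_selection)
    ref = traj[0] if reference is None else reference

    fitted = np.empty((len(traj), len(sel), 3))
    for k, frame in enumerate(traj):
        _, t = superpose_rmsd(frame, ref, fit_sel)
        fitted[k] = apply_transform(frame.coords[sel], t)
    mean_pos = fitted.mean(axis=0)
    dev2 = np.sum((fitted - mean_pos) ** 2, axis=2)
    return np.sqrt(dev2.mean(axis=0))


def sasa(
    frame: Frame,
    params: SasaParams = SasaParams(),
    selection=None,
) -> tuple[float, np.ndarray]:
    """Solvent-accessible surface area of ``selection`` among all atoms.

    All atoms of the frame occlude; area is computed (and summed) only for
    the selected atoms.  Returns (total, per-atom) in Angstrom^2; the
    per-atom array is NaN outside the selection.
    """
    try:
        radii = np.array([params.vdw_radii[e] for e in frame.elements], dtype=float)
    except KeyError as exc:
        raise KeyError(f"no van der Waals radius for element {exc.args[0]!r}") from None
    arr = struc.AtomArray(frame.n_atoms)
    arr.coord[:] = frame.coords
    arr.element = frame.elements.astype("U2")
    # neutral residue names: biotite would otherwise drop solvent residues
    arr.res_name = np.full(frame.n_atoms, "UNK", dtype="U5")
    arr.res_id = np.arange(1, frame.n_atoms + 1)
    mask = None
    if selection is not None:
        mask = np.zeros(frame.n_atoms, dtype=bool)
        mask[np.asarray(selection)] = True
    per_atom = struc.sasa(
        arr,
        probe_radius=params.probe_radius,
        point_number=params.point_number,
        vdw_radii=radii,
        atom_filter=mask,
        ignore_ions=False,
    )
    per_atom = np.asarray(per_atom, dtype=float)
    total = float(np.nansum(per_atom if mask is None else per_atom[mask]))
    return total, per_atom
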