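"""Structure and trajectory I/O with chemical-role annotation.

Coordinates are in Angstrom throughout; boxes are orthorhombic (three edge
lengths) and the minimum-image convention is applied only when a box is
present.  Bonding of hydrogens to heavy atoms is inferred from atom order and
residue membership (never from distances), so role assignment is
deterministic for a given file.

Supported formats: PDB (ATOM/HETATM/MODEL records, via biotite) and plain
multi-frame XYZ.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
from biotite.structure import AtomArray
from biotite.structure.io.pdb import PDBFile

__all__ = [
    "Frame",
    "Topology",
    "Trajectory",
    "ParseError",
    "TopologyError",
    "read_structure",
    "read_trajectory",
    "write_structure",
    "write_trajectory",
    "annotate_fragment",
    "infer_roles",
    "mic_displacement",
    "atom_distance",
    "FRAGMENT_KEYS",
    "ROLE_DONOR",
    "ROLE_ACCEPTOR",
    "ROLE_POLAR_H",
    "ROLE_WATER_O",
    "ROLE_WATER_H",
    "ROLE_OTHER",
]


class ParseError(ValueError):
    """A file did not parse in the expected dialect."""


class TopologyError(ValueError):
    """Atom roles, bonding or the fragment map are inconsistent."""


# Role tags for hydrogen-bond analysis.
ROLE_DONOR = "hb_donor_heavy"
ROLE_ACCEPTOR = "hb_acceptor_heavy"
ROLE_POLAR_H = "polar_hydrogen"
ROLE_WATER_O = "water_oxygen"
ROLE_WATER_H = "water_hydrogen"
ROLE_OTHER = "other"

#: Keys of the catalytic-fragment map: the imidic-acid side-chain carbon,
#: its oxygen and nitrogen heteroatoms, the hydroxyl proton (H*) and the
#: imine proton (H_N).  Indices are 0-based.
FRAGMENT_KEYS = ("CG", "OD", "ND", "HO", "HN")

WATER_RESNAMES = frozenset({"HOH", "WAT", "SOL", "TIP3", "TIP", "SPC", "T3P"})

_KNOWN_ELEMENTS = frozenset(
    "H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Sc Ti V Cr Mn Fe Co "
    "Ni Cu Zn Ga Ge As Se Br Kr Rb Sr Mo Ru Rh Pd Ag Cd I Xe Cs Ba W Pt Au "
    "Hg Pb".split()
)


@dataclass
class Frame:
    """One snapshot: per-atom positions and element symbols.

    Parameters
    ----------
    coords : (n, 3) float array, Angstrom
    elements : length-n sequence of element symbols
    box : optional (3,) array of orthorhombic box edge lengths, Angstrom
    """

    coords: np.ndarray
    elements: np.ndarray
    box: np.ndarray | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must have shape (n, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords must be finite")
        self.elements = np.asarray(self.elements, dtype="U2")
        if len(self.elements) != len(self.coords):
            raise ValueError("elements length must equal number of atoms")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.shape != (3,) or not np.all(self.box > 0):
                raise ValueError("box must be three positive lengths")

    @property
    def n_atoms(self) -> int:
        return len(self.coords)


@dataclass
class Topology:
    """Atom names, residue labels, role tags and hydrogen bonding map.

    ``h_to_heavy`` maps each (polar or water) hydrogen index to the index of
    the single heavy atom it is bonded to.  ``fragment`` is the catalytic
    fragment map (keys :data:`FRAGMENT_KEYS`) and stays ``None`` until
    :func:`annotate_fragment` is called.
    """

    atom_names: list[str]
    res_names: list[str]
    res_ids: np.ndarray
    roles: np.ndarray
    h_to_heavy: dict[int, int] = field(default_factory=dict)
    fragment: dict[str, int] | None = None

    def __post_init__(self):
        n = len(self.atom_names)
        if not (len(self.res_names) == len(self.res_ids) == len(self.roles) == n):
            raise TopologyError("per-atom annotation arrays must share one length")
        self.res_ids = np.asarray(self.res_ids, dtype=int)
        self.roles = np.asarray(self.roles, dtype="U32")
        for h, heavy in self.h_to_heavy.items():
            if not (0 <= h < n and 0 <= heavy < n):
                raise TopologyError("h_to_heavy indices out of range")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def water_oxygens(self) -> np.ndarray:
        return np.flatnonzero(self.roles == ROLE_WATER_O)

    def hydrogens_of(self, heavy: int) -> list[int]:
        return [h for h, hv in self.h_to_heavy.items() if hv == heavy]


@dataclass
class Trajectory:
    """Ordered frames sharing one topology; ``stride_ps`` is ps per frame."""

    frames: list[Frame]
    topology: Topology
    stride_ps: float = 1.0

    def __post_init__(self):
        if self.stride_ps <= 0:
            raise ValueError("stride_ps must be positive")
        counts = {f.n_atoms for f in self.frames}
        if len(counts) > 1:
            raise ValueError("all frames must have identical atom count")
        if self.frames and self.frames[0].n_atoms != self.topology.n_atoms:
            raise ValueError("frame atom count does not match topology")

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, i) -> Frame:
        return self.frames[i]

    def __iter__(self):
        return iter(self.frames)


# ---------------------------------------------------------------------------
# geometry helpers (minimum image)
# ---------------------------------------------------------------------------

def mic_displacement(d: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    """Wrap displacement vector(s) ``d`` by the minimum-image convention."""
    if box is None:
        return d
    return d - box * np.round(d / box)


def atom_distance(frame: Frame, i: int, j: int) -> float:
    d = mic_displacement(frame.coords[j] - frame.coords[i], frame.box)
    return float(np.linalg.norm(d))


# ---------------------------------------------------------------------------
# role inference
# ---------------------------------------------------------------------------

def infer_roles(
    atom_names: list[str],
    res_names: list[str],
    res_ids: np.ndarray,
    elements: np.ndarray,
) -> tuple[np.ndarray, dict[int, int]]:
    """Assign hydrogen-bond roles from residue/atom names.

    Hydrogens are attached to the most recent preceding heavy atom within the
    same residue (standard PDB atom ordering); waters get water roles, other
    N/O atoms become donors when they carry a hydrogen and acceptors
    otherwise.  Raises :class:`TopologyError` for water residues that do not
    consist of exactly one oxygen and two hydrogens.
    """
    n = len(atom_names)
    res_ids = np.asarray(res_ids)
    roles = np.full(n, ROLE_OTHER, dtype="U32")
    h_to_heavy: dict[int, int] = {}

    last_heavy_in_res: int | None = None
    last_res = None
    for i in range(n):
        key = (res_ids[i], res_names[i])
        if key != last_res:
            last_res = key
            last_heavy_in_res = None
        if elements[i] == "H":
            if last_heavy_in_res is not None:
                h_to_heavy[i] = last_heavy_in_res
        else:
            last_heavy_in_res = i

    has_h = set(h_to_heavy.values())
    for i in range(n):
        is_water = res_names[i].upper() in WATER_RESNAMES
        el = elements[i]
        if is_water:
            if el == "O":
                roles[i] = ROLE_WATER_O
            elif el == "H":
                roles[i] = ROLE_WATER_H
        elif el == "H":
            heavy = h_to_heavy.get(i)
            if heavy is not None and elements[heavy] in ("N", "O"):
                roles[i] = ROLE_POLAR_H
        elif el in ("N", "O"):
            roles[i] = ROLE_DONOR if i in has_h else ROLE_ACCEPTOR

    # validate water residues: exactly one O and two H each
    for rid in np.unique(res_ids):
        sel = np.flatnonzero(res_ids == rid)
        if res_names[sel[0]].upper() in WATER_RESNAMES:
            n_o = int(np.sum(roles[sel] == ROLE_WATER_O))
            n_h = int(np.sum(roles[sel] == ROLE_WATER_H))
            if (n_o, n_h) != (1, 2):
                raise TopologyError(
                    f"water residue {rid} has {n_o} oxygen(s) and {n_h} "
                    "hydrogen(s); expected 1 and 2"
                )
    return roles, h_to_heavy


def annotate_fragment(topology: Topology, mapping: dict[str, int]) -> Topology:
    """Return a topology carrying the catalytic imidic-acid fragment map.

    ``mapping`` must provide 0-based indices for all of
    ``CG`` (side-chain carbon), ``OD`` (hydroxyl oxygen), ``ND`` (imine
    nitrogen), ``HO`` (hydroxyl proton H*) and ``HN`` (imine proton).
    In the imidic state the oxygen carries H* and acts as donor while the
    nitrogen is the acceptor; roles are retagged accordingly.
    """
    missing = [k for k in FRAGMENT_KEYS if k not in mapping]
    if missing:
        raise TopologyError(f"fragment map missing atoms: {missing}")
    idx = [int(mapping[k]) for k in FRAGMENT_KEYS]
    for k, i in zip(FRAGMENT_KEYS, idx):
        if not 0 <= i < topology.n_atoms:
            raise TopologyError(f"fragment atom {k} index {i} out of range")
    if len(set(idx)) != len(idx):
        raise TopologyError("fragment map assigns one atom to several names")

    frag = {k: int(mapping[k]) for k in FRAGMENT_KEYS}
    roles = topology.roles.copy()
    h_to_heavy = dict(topology.h_to_heavy)
    roles[frag["OD"]] = ROLE_DONOR
    roles[frag["ND"]] = ROLE_ACCEPTOR
    roles[frag["HO"]] = ROLE_POLAR_H
    roles[frag["HN"]] = ROLE_POLAR_H
    h_to_heavy[frag["HO"]] = frag["OD"]
    h_to_heavy[frag["HN"]] = frag["ND"]
    return replace(topology, roles=roles, h_to_heavy=h_to_heavy, fragment=frag)


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

def _prescan_pdb(path: str) -> None:
    """Validate coordinate fields of ATOM/HETATM records line by line."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM", "HETATM")):
                for lo, hi, what in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
                    fieldtxt = line[lo:hi].strip()
                    try:
                        float(fieldtxt)
                    except ValueError:
                        raise ParseError(
                            f"{path}: line {lineno}: malformed {what} "
                            f"coordinate {fieldtxt!r}"
                        ) from None


def _from_atom_array(arr: AtomArray) -> tuple[Frame, Topology]:
    elements = np.array([e.capitalize() for e in arr.element], dtype="U2")
    for e in elements:
        if e not in _KNOWN_ELEMENTS:
            raise ParseError(f"unknown element symbol {e!r}")
    box = None
    if arr.box is not None:
        lengths = np.diagonal(arr.box)
        if np.all(lengths > 0):
            box = np.asarray(lengths, dtype=float)
    frame = Frame(coords=np.asarray(arr.coord, dtype=float), elements=elements, box=box)
    names = [str(x) for x in arr.atom_name]
    resnames = [str(x) for x in arr.res_name]
    resids = np.asarray(arr.res_id, dtype=int)
    roles, h_to_heavy = infer_roles(names, resnames, resids, elements)
    topo = Topology(names, resnames, resids, roles, h_to_heavy)
    return frame, topo


def _read_pdb_models(path: str) -> tuple[list[np.ndarray], AtomArray]:
    _prescan_pdb(path)
    pdb = PDBFile.read(path)
    n_models = pdb.get_model_count()
    arrays = []
    first = None
    for m in range(1, n_models + 1):
        try:
            arr = pdb.get_structure(model=m, altloc="first")
        except Exception as exc:  # inconsistent model → name the frame
            raise ParseError(f"{path}: model {m}: {exc}") from exc
        if first is None:
            first = arr
        elif arr.array_length() != first.array_length():
            raise ParseError(
                f"{path}: frame {m} has {arr.array_length()} atoms, "
                f"expected {first.array_length()}"
            )
        arrays.append(np.asarray(arr.coord, dtype=float))
    if first is None:
        raise ParseError(f"{path}: no ATOM/HETATM records found")
    return arrays, first


# ---------------------------------------------------------------------------
# XYZ
# ---------------------------------------------------------------------------

def _read_xyz_frames(path: str) -> list[tuple[list[str], np.ndarray]]:
    frames = []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    lineno = 0
    nframe = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        nframe += 1
        try:
            n = int(lines[i].strip())
        except ValueError:
            raise ParseError(
                f"{path}: line {i + 1}: expected atom count, got {lines[i].strip()!r}"
            ) from None
        if i + 1 + n + 1 > len(lines) + 1:
            raise ParseError(f"{path}: frame {nframe}: truncated (expected {n} atoms)")
        symbols, coords = [], []
        for j in range(n):
            lineno = i + 2 + j
            if lineno >= len(lines):
                raise ParseError(f"{path}: frame {nframe}: truncated (expected {n} atoms)")
            parts = lines[lineno].split()
            if len(parts) < 4:
                raise ParseError(f"{path}: line {lineno + 1}: malformed XYZ record")
            sym = parts[0].capitalize()
            if sym not in _KNOWN_ELEMENTS:
                raise ParseError(f"{path}: line {lineno + 1}: unknown element {parts[0]!r}")
            try:
                coords.append([float(parts[1]), float(parts[2]), float(parts[3])])
            except ValueError:
                raise ParseError(
                    f"{path}: line {lineno + 1}: malformed coordinate"
                ) from None
            symbols.append(sym)
        frames.append((symbols, np.asarray(coords)))
        i += 2 + n
    if not frames:
        raise ParseError(f"{path}: empty XYZ file")
    return frames


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def _guess_format(path: str, fmt: str | None) -> str:
    if fmt is not None:
        return fmt.lower()
    ext = os.path.splitext(path)[1].lower().lstrip(".")
    if ext in ("pdb", "xyz"):
        return ext
    raise ValueError(f"cannot infer format from {path!r}; pass format=")


def read_structure(path: str, format: str | None = None) -> tuple[Frame, Topology]:
    """Read one structure; roles inferred from residue/atom names.

    The catalytic fragment stays unset until :func:`annotate_fragment`.
    """
    fmt = _guess_format(path, format)
    if fmt == "pdb":
        coords, arr = _read_pdb_models(path)
        frame, topo = _from_atom_array(arr)
        return Frame(coords[0], frame.elements, frame.box), topo
    if fmt == "xyz":
        symbols, coords = _read_xyz_frames(path)[0]
        frame = Frame(coords, np.array(symbols, dtype="U2"))
        names = [f"{s}{i + 1}" for i, s in enumerate(symbols)]
        resnames = ["UNK"] * len(symbols)
        resids = np.ones(len(symbols), dtype=int)
        roles, h_to_heavy = infer_roles(names, resnames, resids, frame.elements)
        return frame, Topology(names, resnames, resids, roles, h_to_heavy)
    raise ValueError(f"unsupported format {fmt!r}")


def read_trajectory(
    path: str,
    topology: Topology,
    format: str | None = None,
    stride_ps: float = 1.0,
) -> Trajectory:
    """Read a multi-MODEL PDB or multi-frame XYZ against a known topology."""
    fmt = _guess_format(path, format)
    if fmt == "pdb":
        coords, arr = _read_pdb_models(path)
        elements = np.array([e.capitalize() for e in arr.element], dtype="U2")
        frames = [Frame(c, elements) for c in coords]
    elif fmt == "xyz":
        raw = _read_xyz_frames(path)
        frames = []
        for k, (symbols, coords) in enumerate(raw, start=1):
            if len(symbols) != topology.n_atoms:
                raise ParseError(
                    f"{path}: frame {k} has {len(symbols)} atoms, "
                    f"expected {topology.n_atoms}"
                )
            frames.append(Frame(coords, np.array(symbols, dtype="U2")))
    else:
        raise ValueError(f"unsupported format {fmt!r}")
    if frames[0].n_atoms != topology.n_atoms:
        raise ParseError(
            f"{path}: frame 1 has {frames[0].n_atoms} atoms, "
            f"expected {topology.n_atoms}"
        )
    return Trajectory(frames, topology, stride_ps=stride_ps)


def _to_atom_array(frame: Frame, topology: Topology | None) -> AtomArray:
    n = frame.n_atoms
    arr = AtomArray(n)
    arr.coord[:] = frame.coords
    arr.element = frame.elements.astype("U2")
    if topology is not None:
        arr.atom_name = np.array(topology.atom_names, dtype="U6")
        arr.res_name = np.array(topology.res_names, dtype="U5")
        arr.res_id = topology.res_ids.copy()
    else:
        arr.atom_name = frame.elements.astype("U6")
        arr.res_name = np.full(n, "UNK", dtype="U5")
        arr.res_id = np.ones(n, dtype=int)
    arr.hetero = np.full(n, True)
    return arr


def write_structure(
    path: str,
    frame: Frame | list[Frame],
    topology: Topology | None = None,
    format: str | None = None,
) -> None:
    """Write one frame (or a list, as MODELs / concatenated XYZ frames)."""
    fmt = _guess_format(path, format)
    frames = frame if isinstance(frame, list) else [frame]
    if fmt == "pdb":
        pdb = PDBFile()
        if len(frames) == 1:
            pdb.set_structure(_to_atom_array(frames[0], topology))
        else:
            from biotite.structure import stack

            pdb.set_structure(stack([_to_atom_array(f, topology) for f in frames]))
        pdb.write(path)
    elif fmt == "xyz":
        with open(path, "w") as fh:
            for f in frames:
                fh.write(f"{f.n_atoms}\n")
                fh.write("generated by protorelay\n")
                for el, (x, y, z) in zip(f.elements, f.coords):
                    fh.write(f"{el:2s} {x:14.6f} {y:14.6f} {z:14.6f}\n")
    else:
        raise ValueError(f"unsupported format {fmt!r}")


def write_trajectory(path: str, traj: Trajectory, format: str | None = None) -> None:
    write_structure(path, list(traj.frames), traj.topology, format=format)
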