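"""Radial water-count profiles around the catalytic fragment.

A water molecule is represented by its oxygen atom; a water counts toward a
shell when its oxygen lies within (inclusive, <=) the cutoff distance of the
centre atom, with the minimum-image convention applied when the frame has a
box.  The default cutoffs run from 1 to 10 Angstrom in 0.5 Angstrom steps,
plus 15 and 20 Angstrom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import Frame, Topology, TopologyError, Trajectory, mic_displacement

__all__ = ["ShellProfile", "water_counts", "shell_profile", "DEFAULT_CUTOFFS"]

DEFAULT_CUTOFFS = tuple(np.arange(1.0, 10.0 + 1e-9, 0.5)) + (15.0, 20.0)


@dataclass
class ShellProfile:
    """Per-cutoff mean and sample SD (n-1) of water counts over frames."""

    cutoffs: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    counts: np.ndarray  # (n_frames, n_cutoffs)

    def __post_init__(self):
        if np.any(np.diff(self.cutoffs) <= 0):
            raise ValueError("cutoffs must be strictly increasing")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"cutoff": self.cutoffs, "mean": self.mean, "sd": self.sd}
        )


def water_counts(
    frame: Frame,
    topology: Topology,
    center: int,
    cutoffs=DEFAULT_CUTOFFS,
) -> np.ndarray:
    """Number of water oxygens within each cutoff of atom ``center``."""
    cutoffs = np.asarray(cutoffs, dtype=float)
    if np.any(np.diff(cutoffs) <= 0):
        raise ValueError("cutoffs must be strictly increasing")
    waters = topology.water_oxygens
    if len(waters) == 0:
        return np.zeros(len(cutoffs), dtype=int)
    d = mic_displacement(frame.coords[waters] - frame.coords[center], frame.box)
    r = np.linalg.norm(d, axis=1)
    return np.sum(r[:, None] <= cutoffs[None, :], axis=0)


def shell_profile(
    traj: Trajectory,
    topology: Topology | None = None,
    center: int | None = None,
    cutoffs=DEFAULT_CUTOFFS,
) -> ShellProfile:
    """Shell profile over a trajectory, centred on the fragment carbon.

    ``center`` defaults to the annotated CG atom of the catalytic fragment.
    """
    topo = topology if topology is not None else traj.topology
    if center is None:
        if topo.fragment is None:
            raise TopologyError("no center given and fragment not annotated")
        center = topo.fragment["CG"]
    if len(traj) < 1:
        raise ValueError("trajectory must contain at least one frame")
    counts = np.array([water_counts(f, topo, center, cutoffs) for f in traj])
    mean = counts.mean(axis=0)
    sd = counts.std(axis=0, ddof=1) if len(traj) > 1 else np.zeros(counts.shape[1])
    return ShellProfile(np.asarray(cutoffs, dtype=float), mean, sd, counts)
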