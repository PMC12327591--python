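"""Spatial sphere neighborhoods around each residue's C-alpha.

On a chosen target frame (by default the first), one sphere is built
per residue; its atom membership is fixed there and reused for every
frame comparison, so the same local neighborhood is tracked over time.

Two membership modes are provided because "within distance d" can be
read at two granularities:

``residue_ca``
    residue j belongs to residue i's sphere iff their C-alpha–C-alpha
    distance on the target frame is <= d; all (heavy) atoms of member
    residues are included. This is the default.
``atom_any``
    an individual atom belongs iff its own distance to residue i's
    C-alpha is <= d.

The radius d is restricted to 2–8 Angstrom. The closed ball (<=) is
used so boundary atoms are treated deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .trajectory import Trajectory

__all__ = [
    "RADIUS_MIN",
    "RADIUS_MAX",
    "SphereParams",
    "SphereDefinition",
    "ConfigError",
    "check_radius",
    "build_spheres",
]

RADIUS_MIN = 2.0
RADIUS_MAX = 8.0

MEMBERSHIP_MODES = ("residue_ca", "atom_any")


class ConfigError(ValueError):
    """Raised for analysis parameters outside their documented bounds."""


def check_radius(d: float) -> float:
    """Validate the sphere radius d (Angstrom) against its 2–8 bounds."""
    d = float(d)
    if not np.isfinite(d) or not RADIUS_MIN <= d <= RADIUS_MAX:
        raise ConfigError(
            f"sphere radius must lie within {RADIUS_MIN:g} to {RADIUS_MAX:g} Angstrom, got {d:g}"
        )
    return d


@dataclass(frozen=True)
class SphereParams:
    """Sphere construction parameters.

    radius_d : float
        cutoff distance d in Angstrom, 2 <= d <= 8.
    target_frame : int
        0-based index of the frame on which membership is fixed.
    membership_mode : str
        "residue_ca" (default) or "atom_any"; see module docstring.
    include_hydrogens : bool
        whether hydrogen atoms count as sphere members (default False,
        since trajectories may or may not carry them).
    """

    radius_d: float = 4.0
    target_frame: int = 0
    membership_mode: str = "residue_ca"
    include_hydrogens: bool = False

    def __post_init__(self) -> None:
        check_radius(self.radius_d)
        if self.membership_mode not in MEMBERSHIP_MODES:
            raise ConfigError(
                f"membership_mode must be one of {MEMBERSHIP_MODES}, got {self.membership_mode!r}"
            )
        if self.target_frame < 0:
            raise ConfigError("target_frame must be >= 0")


@dataclass(frozen=True)
class SphereDefinition:
    """Fixed atom membership of one residue's sphere.

    ``member_atom_indices`` are sorted flat topology indices;
    ``member_residues`` the sorted residue indices owning them. The
    center residue always belongs to its own sphere.
    """

    center_residue: int
    member_atom_indices: np.ndarray
    member_residues: np.ndarray


def build_spheres(traj: Trajectory, params: SphereParams) -> list[SphereDefinition]:
    """Build one sphere per residue on the target frame.

    Membership is computed once there and never updated. The result is
    deterministic (sorted indices) and independent of the spatial-index
    internals; a KD-tree only accelerates the fixed-radius query.
    """
    if not 0 <= params.target_frame < traj.n_frames:
        raise ConfigError(
            f"target frame {params.target_frame} out of range for {traj.n_frames} frame(s)"
        )
    d = check_radius(params.radius_d)
    top = traj.topology
    n_res = traj.n_residues

    res_atom_idx = top.residue_atom_indices()
    atom_residue = np.empty(top.atom_count, dtype=int)
    hydrogen_mask = np.zeros(top.atom_count, dtype=bool)
    ca_atom_idx = np.empty(n_res, dtype=int)
    for r, res in enumerate(top.residues):
        idx = res_atom_idx[r]
        atom_residue[idx] = r
        ca_atom_idx[r] = idx[res.ca_index]
        for local, atom in enumerate(res.atoms):
            if atom.is_hydrogen:
                hydrogen_mask[idx[local]] = True

    frame = traj.frames[params.target_frame]
    ca_xyz = frame[ca_atom_idx]

    spheres: list[SphereDefinition] = []
    if params.membership_mode == "residue_ca":
        tree = cKDTree(ca_xyz)
        neighbor_lists = tree.query_ball_point(ca_xyz, r=d)
        for r in range(n_res):
            members = np.array(sorted(set(neighbor_lists[r]) | {r}), dtype=int)
            atom_idx = np.concatenate([res_atom_idx[m] for m in members])
            if not params.include_hydrogens:
                atom_idx = atom_idx[~hydrogen_mask[atom_idx]]
            spheres.append(
                SphereDefinition(
                    center_residue=r,
                    member_atom_indices=np.sort(atom_idx),
                    member_residues=members,
                )
            )
    else:  # atom_any
        candidate = np.arange(top.atom_count)
        if not params.include_hydrogens:
            candidate = candidate[~hydrogen_mask]
        tree = cKDTree(frame[candidate])
        neighbor_lists = tree.query_ball_point(ca_xyz, r=d)
        for r in range(n_res):
            atom_idx = set(candidate[neighbor_lists[r]])
            own = res_atom_idx[r]
            if not params.include_hydrogens:
                own = own[~hydrogen_mask[own]]
            atom_idx |= set(own)  # the center residue always belongs
            atom_arr = np.array(sorted(atom_idx), dtype=int)
            spheres.append(
                SphereDefinition(
                    center_residue=r,
                    member_atom_indices=atom_arr,
                    member_residues=np.unique(atom_residue[atom_arr]),
                )
            )
    return spheres
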