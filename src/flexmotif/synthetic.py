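"""Deterministic synthetic structures and trajectories for testing.

The generator emulates the statistical shape the fluctuation heuristic
assumes: a mostly stable fold, optional global rigid-body drift (as in
un-fitted MD output), and a localized flexible window whose atoms
receive independent Gaussian displacements each frame. Chains are
poly-alanine (N, CA, C, O, CB per residue) at idealized geometry —
the smallest standard residue that still has a side-chain atom, so
missing-atom validation stays meaningful.

Noise is drawn independently per atom and per frame (not a random
walk), which makes the frame-to-frame displacement distribution
stationary and analytically checkable: the expected squared
frame-to-frame displacement of a perturbed atom is 6*sigma^2.
Everything is a pure function of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from io import StringIO

import numpy as np

from .structure_io import AtomRecord, Residue, ResidueId, StructureModel, write_pdb
from .trajectory import Trajectory, write_trajectory

__all__ = ["SynthSpec", "make_structure", "make_trajectory", "structure_pdb", "trajectory_pdb"]

#: Ideal helix: 1.5 A rise and 100 degree turn per residue.
HELIX_RISE = 1.5
HELIX_TURN = np.deg2rad(100.0)
HELIX_RADIUS = 2.3
#: Extended chain: 3.5 A C-alpha spacing along x.
EXTENDED_SPACING = 3.5

# Offsets of the other heavy atoms from the C-alpha, in the residue's
# local frame (rotated with the helix turn so geometry stays chain-like).
_ATOM_OFFSETS = {
    "N": np.array([-1.20, -0.80, -0.20]),
    "C": np.array([1.25, -0.60, 0.30]),
    "O": np.array([2.10, -1.30, 0.10]),
    "CB": np.array([0.10, 1.40, -0.50]),
}
_ATOM_ORDER = ("N", "CA", "C", "O", "CB")
_ELEMENTS = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C"}


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of one synthetic trajectory.

    n_residues, n_frames : int
        chain length and frame count (each >= 1).
    backbone_geometry : str
        "ideal_helix" or "extended".
    translation : tuple of 3 floats
        per-frame rigid translation in Angstrom.
    rotation_angle : float
        per-frame rigid rotation in radians about the z axis through
        the base structure's centroid.
    perturbed_window : (start, end) 1-based inclusive residue range, or None
        residues whose atoms receive Gaussian noise each frame.
    perturbation_sigma : float
        per-component standard deviation of that noise, Angstrom.
    seed : int
        seed for the noise generator; with sigma = 0 output is
        seed-independent.
    """

    n_residues: int = 30
    n_frames: int = 5
    backbone_geometry: str = "ideal_helix"
    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    rotation_angle: float = 0.0
    perturbed_window: tuple[int, int] | None = None
    perturbation_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_residues < 1:
            raise ValueError("n_residues must be >= 1")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.backbone_geometry not in ("ideal_helix", "extended"):
            raise ValueError(f"unknown backbone geometry {self.backbone_geometry!r}")
        if self.perturbation_sigma < 0:
            raise ValueError("perturbation_sigma must be >= 0")
        if self.perturbed_window is not None:
            lo, hi = self.perturbed_window
            if not (1 <= lo <= hi <= self.n_residues):
                raise ValueError(
                    f"perturbed_window {self.perturbed_window} outside [1, {self.n_residues}]"
                )


def _rot_z(angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def make_structure(spec: SynthSpec) -> StructureModel:
    """Build the base poly-alanine chain of the spec's geometry."""
    residues: list[Residue] = []
    serial = 0
    for i in range(spec.n_residues):
        if spec.backbone_geometry == "ideal_helix":
            angle = i * HELIX_TURN
            ca = np.array(
                [HELIX_RADIUS * np.cos(angle), HELIX_RADIUS * np.sin(angle), HELIX_RISE * i]
            )
            local = _rot_z(angle)
        else:
            ca = np.array([EXTENDED_SPACING * i, 0.0, 0.0])
            local = np.eye(3)
        atoms = []
        for name in _ATOM_ORDER:
            serial += 1
            xyz = ca if name == "CA" else ca + local @ _ATOM_OFFSETS[name]
            atoms.append(
                AtomRecord(
                    serial=serial,
                    name=name,
                    element=_ELEMENTS[name],
                    alt_loc="",
                    occupancy=1.0,
                    b_factor=0.0,
                    coords=np.round(xyz, 3),  # PDB precision, so round-trips are exact
                )
            )
        residues.append(
            Residue(id=ResidueId("A", i + 1, ""), res_name="ALA", atoms=atoms, ca_index=1)
        )
    return StructureModel(residues=residues, source_label="synthetic")


def make_trajectory(spec: SynthSpec) -> Trajectory:
    """Build the trajectory: rigid drift plus windowed Gaussian noise.

    Frame k is the base structure under the k-fold composition of the
    per-frame rigid motion (rotation about the base centroid, then
    translation); atoms of residues inside ``perturbed_window`` are
    additionally displaced by fresh Gaussian noise in every frame.
    """
    top = make_structure(spec)
    base = top.coords()
    centroid = base.mean(axis=0)
    rot = _rot_z(spec.rotation_angle)
    trans = np.asarray(spec.translation, dtype=float)

    perturbed_atoms = np.zeros(base.shape[0], dtype=bool)
    if spec.perturbed_window is not None:
        lo, hi = spec.perturbed_window
        for r, idx in zip(range(spec.n_residues), top.residue_atom_indices()):
            if lo - 1 <= r <= hi - 1:
                perturbed_atoms[idx] = True

    rng = np.random.default_rng(spec.seed)
    frames = np.empty((spec.n_frames, base.shape[0], 3))
    current = base
    for k in range(spec.n_frames):
        frame = current.copy()
        if spec.perturbation_sigma > 0 and perturbed_atoms.any():
            noise = rng.normal(0.0, spec.perturbation_sigma, size=(int(perturbed_atoms.sum()), 3))
            frame[perturbed_atoms] += noise
        frames[k] = frame
        # Apply rotation and translation only when present, so a pure
        # translation (or no motion) stays exact in floating point.
        if spec.rotation_angle != 0.0:
            current = (current - centroid) @ rot.T + centroid
        if np.any(trans != 0.0):
            current = current + trans
    return Trajectory(topology=top, frames=frames)


def structure_pdb(spec: SynthSpec) -> str:
    """The base structure as PDB text (deterministic in the spec)."""
    buf = StringIO()
    write_pdb(make_structure(spec), buf)
    return buf.getvalue()


def trajectory_pdb(spec: SynthSpec) -> str:
    """The trajectory as multi-model PDB text (deterministic in spec+seed)."""
    buf = StringIO()
    write_trajectory(make_trajectory(spec), buf)
    return buf.getvalue()
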