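"""MD trajectories as multi-model PDB files with one shared topology.

The first model of the file defines the topology (after validation);
every later model must carry exactly the same atoms, matched by
(residue id, atom name). Frames are stored as an (F, N, 3) coordinate
array aligned index-for-index with the topology atoms, so per-sphere
extraction is a plain fancy-index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import IO, Sequence

import numpy as np

from .structure_io import (
    RawModel,
    StructureModel,
    ValidationReport,
    format_atom_line,
    parse_pdb,
    validate_structure,
)

__all__ = ["Trajectory", "TrajectoryError", "read_trajectory", "write_trajectory", "frame_coords"]


class TrajectoryError(ValueError):
    """Raised for topology mismatches and invalid frame access."""


@dataclass
class Trajectory:
    """An ordered list of frames sharing one atom topology.

    ``frames`` has shape (F, N, 3) in Angstrom; row order equals the
    flat atom order of ``topology``. One frame is permitted for storage,
    but fluctuation analysis requires at least two.
    """

    topology: StructureModel
    frames: np.ndarray
    frame_labels: list[str] = field(default_factory=list)
    validation: ValidationReport | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise TrajectoryError("frames must have shape (F, N, 3)")
        if self.frames.shape[1] != self.topology.atom_count:
            raise TrajectoryError(
                f"frame atom count {self.frames.shape[1]} does not match "
                f"topology atom count {self.topology.atom_count}"
            )
        if not self.frame_labels:
            self.frame_labels = [str(i + 1) for i in range(self.n_frames)]
        if len(self.frame_labels) != self.n_frames:
            raise TrajectoryError("one label per frame required")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]

    @property
    def n_residues(self) -> int:
        return len(self.topology.residues)


def _atom_keys(raw: RawModel) -> dict[tuple[str, int, str, str], np.ndarray]:
    out: dict[tuple[str, int, str, str], np.ndarray] = {}
    for rec in raw.records:
        key = (rec.chain_id, rec.seq_num, rec.insertion_code, rec.name)
        out.setdefault(key, rec.coords)  # first occurrence wins (alt-locs)
    return out


def read_trajectory(stream: IO[str]) -> Trajectory:
    """Read a multi-model PDB stream as a trajectory.

    Model 1 is validated and defines the topology. Later models are
    matched to it by (residue id, atom name); atoms that validation
    removed from model 1 (waters, ligands, rejected residues) are
    ignored in later models too, but a topology atom missing from a
    later model — or a new protein atom appearing there — is an error.
    """
    raw_models = parse_pdb(stream)
    topology, report = validate_structure(raw_models[0])

    keys: list[tuple[str, int, str, str]] = []
    for _, res, atom in topology.iter_atoms():
        keys.append((res.id.chain_id, res.id.seq_num, res.id.insertion_code, atom.name))
    key_set = set(keys)
    dropped_in_model1 = {
        (r.chain_id, r.seq_num, r.insertion_code, r.name) for r in raw_models[0].records
    } - key_set

    frames = [topology.coords()]
    labels = [raw_models[0].label]
    for k, raw in enumerate(raw_models[1:], start=2):
        coords_by_key = _atom_keys(raw)
        missing = key_set - coords_by_key.keys()
        extra = coords_by_key.keys() - key_set - dropped_in_model1
        if missing or extra:
            detail = []
            if missing:
                detail.append(f"{len(missing)} topology atom(s) absent")
            if extra:
                detail.append(f"{len(extra)} unknown atom(s) present")
            raise TrajectoryError(f"inconsistent topology at frame {k}: " + "; ".join(detail))
        frames.append(np.array([coords_by_key[key] for key in keys]))
        labels.append(raw.label)
    return Trajectory(
        topology=topology,
        frames=np.stack(frames),
        frame_labels=labels,
        validation=report,
    )


def write_trajectory(
    traj: Trajectory,
    stream: IO[str],
    b_factors: np.ndarray | None = None,
) -> None:
    """Write one MODEL/ENDMDL block per frame.

    ``b_factors`` (F, N) optionally overrides the per-atom temperature
    factors frame by frame (used for fluctuation annotation).
    """
    if traj.n_frames == 0:
        raise TrajectoryError("cannot write a trajectory with zero frames")
    if b_factors is not None:
        b_factors = np.asarray(b_factors, dtype=float)
        if b_factors.shape != (traj.n_frames, traj.n_atoms):
            raise TrajectoryError("b_factors must have shape (F, N)")
    for f in range(traj.n_frames):
        stream.write(f"MODEL     {f + 1:>4d}\n")
        serial = 0
        prev_chain: str | None = None
        for i, res, atom in traj.topology.iter_atoms():
            if prev_chain is not None and res.id.chain_id != prev_chain:
                stream.write("TER\n")
            prev_chain = res.id.chain_id
            serial += 1
            stream.write(
                format_atom_line(
                    serial,
                    atom,
                    res,
                    coords=traj.frames[f, i],
                    b_factor=None if b_factors is None else b_factors[f, i],
                )
            )
        stream.write("TER\nENDMDL\n")
    stream.write("END\n")


def frame_coords(
    traj: Trajectory, frame_index: int, atom_indices: Sequence[int] | np.ndarray
) -> np.ndarray:
    """Coordinates of the given topology atoms in one frame.

    The stable-ordering contract: the same ``atom_indices`` yield rows
    in the same order for every frame.
    """
    if not 0 <= frame_index < traj.n_frames:
        raise TrajectoryError(
            f"frame index {frame_index} out of range (0..{traj.n_frames - 1})"
        )
    idx = np.asarray(atom_indices, dtype=int)
    if idx.size and (idx.min() < 0 or idx.max() >= traj.n_atoms):
        raise TrajectoryError("atom index out of range")
    return traj.frames[frame_index, idx].reshape(-1, 3)
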