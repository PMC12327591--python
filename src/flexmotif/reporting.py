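"""Serialize analysis results: score CSV, motif report, annotated PDB.

Visualization is realized through the temperature-factor (B-factor)
column of per-frame PDB output — every molecular viewer can color by
it — plus plain-text residue selection strings in a PyMOL-style
grammar, instead of an embedded web viewer.
"""

from __future__ import annotations

from dataclasses import dataclass
from io import StringIO
from typing import IO

import numpy as np
import pandas as pd

from .fluctuation import MotifSet, ScoreMatrix
from .neighborhood import SphereDefinition
from .trajectory import Trajectory, write_trajectory

__all__ = [
    "FLAG_B_FACTOR",
    "AnnotatedTrajectory",
    "write_score_csv",
    "read_score_csv",
    "write_motif_report",
    "annotate_frames",
    "write_annotated_trajectory",
    "viewer_selection_strings",
]

#: Sentinel written to flagged atoms in flag mode: the largest value the
#: PDB fixed-width 6.2 temperature-factor field can hold.
FLAG_B_FACTOR = 99.99


def _residue_label(rid, res_name: str) -> str:
    return f"{rid.chain_id}:{rid.seq_num}:{rid.insertion_code}:{res_name}"


def write_score_csv(matrix: ScoreMatrix, stream: IO[str], res_names: list[str] | None = None) -> None:
    """Write the R x (F-1) RMSD score matrix as RFC-4180 CSV.

    Header row holds the transition labels — the later frame of each
    consecutive pair, 1-based, so columns run "2" .. "F". The first
    column identifies each residue as "chain:seqnum:icode:resname".
    Scores are fixed-point with 4 decimals (Angstrom).
    """
    if res_names is None:
        res_names = ["" for _ in matrix.residue_ids]
    index = [_residue_label(rid, rn) for rid, rn in zip(matrix.residue_ids, res_names)]
    columns = [str(t + 2) for t in range(matrix.n_transitions)]
    df = pd.DataFrame(matrix.scores, index=index, columns=columns)
    df.index.name = "residue"
    df.to_csv(stream, float_format="%.4f", lineterminator="\n")


def read_score_csv(stream: IO[str]) -> pd.DataFrame:
    """Parse a score CSV back into a residues x transitions DataFrame."""
    return pd.read_csv(stream, index_col=0)


def write_motif_report(
    motifs: MotifSet,
    spheres: list[SphereDefinition],
    matrix: ScoreMatrix,
    stream: IO[str],
) -> None:
    """Write the selected motifs as a tab-separated report.

    Columns: rank, residue id, transition as a 1-based "frame a->b"
    pair, sphere RMSD score (Angstrom, 4 decimals), and the residue ids
    of all sphere members.
    """
    stream.write("rank\tresidue\ttransition\tscore_A\tsphere_members\n")
    for m in motifs.motifs:
        members = spheres[m.residue_index].member_residues
        member_ids = ",".join(str(matrix.residue_ids[r]) for r in members)
        stream.write(
            f"{m.rank}\t{m.residue}\tframe {m.transition + 1}->{m.transition + 2}"
            f"\t{m.score:.4f}\t{member_ids}\n"
        )


@dataclass
class AnnotatedTrajectory:
    """A trajectory plus per-frame B-factor annotation.

    Coordinates are shared with (and identical to) the source
    trajectory; only the temperature-factor channel differs.
    """

    trajectory: Trajectory
    b_factors: np.ndarray  # (F, N)


def annotate_frames(
    traj: Trajectory,
    motifs: MotifSet,
    spheres: list[SphereDefinition],
    mode: str = "flag",
) -> AnnotatedTrajectory:
    """Mark motif sphere atoms in the B-factor channel, frame by frame.

    For a motif (residue r, transition t) the member atoms of sphere r
    are marked in the later frame of the pair (1-based frame t+2).
    Frame 1 carries the union of all motif spheres as an overview of
    every high-fluctuation region on the input structure. ``mode``
    "flag" writes the sentinel 99.99, "score" writes the sphere score.
    """
    if mode not in ("flag", "score"):
        raise ValueError(f"mode must be 'flag' or 'score', got {mode!r}")
    b = np.zeros((traj.n_frames, traj.n_atoms))
    for m in motifs.motifs:
        if m.residue_index >= len(spheres) or m.transition + 1 >= traj.n_frames:
            raise ValueError("motif set inconsistent with trajectory/spheres")
        idx = spheres[m.residue_index].member_atom_indices
        value = FLAG_B_FACTOR if mode == "flag" else m.score
        later_frame = m.transition + 1  # 0-based index of 1-based frame t+2
        b[later_frame, idx] = np.maximum(b[later_frame, idx], value)
        b[0, idx] = np.maximum(b[0, idx], value)
    return AnnotatedTrajectory(trajectory=traj, b_factors=b)


def write_annotated_trajectory(annotated: AnnotatedTrajectory, stream: IO[str]) -> None:
    write_trajectory(annotated.trajectory, stream, b_factors=annotated.b_factors)


def _ranges(nums: list[int]) -> str:
    """Compress sorted residue numbers: contiguous 4,5,6 -> "4-6",
    non-contiguous 4,6 -> "4+6" (PyMOL-style)."""
    parts: list[str] = []
    start = prev = nums[0]
    for n in nums[1:] + [None]:  # type: ignore[list-item]
        if n is not None and n == prev + 1:
            prev = n
            continue
        parts.append(str(start) if start == prev else f"{start}-{prev}")
        if n is not None:
            start = prev = n
    return "+".join(parts)


def viewer_selection_strings(
    motifs: MotifSet,
    spheres: list[SphereDefinition],
    matrix: ScoreMatrix,
) -> list[str]:
    """One selection expression per annotated frame.

    Each string selects the motif sphere residues of that frame in a
    generic "chain X and resi a-b" grammar (multiple chains joined with
    " or "); entry 0 is the frame-1 overview selecting the union over
    all motifs. Residue numbers are deduplicated and sorted.
    """
    if not motifs.motifs:
        return []
    per_frame: dict[int, set[int]] = {0: set()}
    for m in motifs.motifs:
        members = set(spheres[m.residue_index].member_residues.tolist())
        per_frame.setdefault(m.transition + 1, set()).update(members)
        per_frame[0].update(members)
    out = []
    for frame in sorted(per_frame):
        by_chain: dict[str, set[int]] = {}
        for r in per_frame[frame]:
            rid = matrix.residue_ids[r]
            by_chain.setdefault(rid.chain_id, set()).add(rid.seq_num)
        clauses = [
            f"chain {chain} and resi {_ranges(sorted(nums))}"
            for chain, nums in sorted(by_chain.items())
        ]
        out.append(" or ".join(f"({c})" for c in clauses) if len(clauses) > 1 else clauses[0])
    return out


def selection_strings_text(
    motifs: MotifSet, spheres: list[SphereDefinition], matrix: ScoreMatrix
) -> str:
    """Selection strings with their 1-based frame numbers, one per line."""
    if not motifs.motifs:
        return ""
    frames = sorted({0} | {m.transition + 1 for m in motifs.motifs})
    lines = [
        f"frame {f + 1}\t{sel}"
        for f, sel in zip(frames, viewer_selection_strings(motifs, spheres, matrix))
    ]
    return "\n".join(lines) + "\n"


def score_csv_string(matrix: ScoreMatrix, res_names: list[str] | None = None) -> str:
    buf = StringIO()
    write_score_csv(matrix, buf, res_names)
    return buf.getvalue()
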