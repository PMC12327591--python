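"""Shared fixtures: hand-written PDB snippets and synthetic trajectories."""

from __future__ import annotations

from io import StringIO

import numpy as np
import pytest

from flexmotif.synthetic import SynthSpec, make_trajectory


def pdb_atom(
    serial: int,
    name: str,
    res_name: str,
    chain: str,
    seq: int,
    x: float,
    y: float,
    z: float,
    record: str = "ATOM",
    occupancy: float = 1.0,
    b: float = 0.0,
    alt_loc: str = " ",
    element: str | None = None,
) -> str:
    el = element if element is not None else name[0]
    nm = f" {name:<3s}" if len(name) < 4 else name
    return (
        f"{record:<6s}{serial:>5d} {nm}{alt_loc}{res_name:>3s} {chain}"
        f"{seq:>4d}    {x:>8.3f}{y:>8.3f}{z:>8.3f}{occupancy:>6.2f}{b:>6.2f}"
        f"          {el:>2s}"
    )


def gly_residue(serial0: int, chain: str, seq: int, origin=(0.0, 0.0, 0.0)) -> list[str]:
    """A complete glycine (backbone-only standard residue)."""
    x, y, z = origin
    return [
        pdb_atom(serial0, "N", "GLY", chain, seq, x - 1.2, y + 0.5, z),
        pdb_atom(serial0 + 1, "CA", "GLY", chain, seq, x, y, z),
        pdb_atom(serial0 + 2, "C", "GLY", chain, seq, x + 1.3, y + 0.4, z),
        pdb_atom(serial0 + 3, "O", "GLY", chain, seq, x + 2.2, y - 0.4, z),
    ]


def as_stream(lines: list[str]) -> StringIO:
    return StringIO("\n".join(lines) + "\n")


@pytest.fixture
def three_gly_with_waters() -> StringIO:
    lines: list[str] = []
    s = 1
    for i in range(3):
        lines += gly_residue(s, "A", i + 1, origin=(3.8 * i, 0.0, 0.0))
        s += 4
    for w in range(10):
        lines.append(
            pdb_atom(s + w, "O", "HOH", "A", 100 + w, 20.0 + w, 20.0, 20.0, record="HETATM")
        )
    return as_stream(lines)


@pytest.fixture
def static_trajectory():
    return make_trajectory(SynthSpec(n_residues=8, n_frames=4))


@pytest.fixture
def translated_trajectory():
    return make_trajectory(
        SynthSpec(n_residues=10, n_frames=4, translation=(3.0, 4.0, 0.0))
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)
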