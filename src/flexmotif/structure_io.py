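"""Read, validate and write protein structures in PDB format.

Validation follows the cleaning rules of the fluctuation-analysis
workflow: non-protein chains, ligands, ions and waters are discarded;
amino acids missing any heavy atom of their standard chemical
composition (or their C-alpha) are rejected; every removal is recorded
in a :class:`ValidationReport` that can be written out as a plain-text
log.

The parser is a fixed-column ATOM/HETATM reader with per-line error
recovery: a record whose coordinate fields fail numeric parsing is
skipped and noted as a format anomaly instead of aborting the read.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import IO, Iterable

import numpy as np

__all__ = [
    "AtomRecord",
    "ResidueId",
    "Residue",
    "StructureModel",
    "ValidationReport",
    "RawAtom",
    "RawModel",
    "StructureError",
    "parse_pdb",
    "validate_structure",
    "read_structure",
    "write_pdb",
    "write_validation_log",
    "STANDARD_AMINO_ACIDS",
    "RESIDUE_HEAVY_ATOMS",
]


class StructureError(ValueError):
    """Raised when a structure cannot be parsed or validated."""


# ---------------------------------------------------------------------------
# Chemical reference data
# ---------------------------------------------------------------------------

#: Heavy (non-hydrogen) atoms required for each standard amino acid.
#: Backbone N, CA, C, O plus the full side chain; terminal OXT is optional.
_BACKBONE = ("N", "CA", "C", "O")

_SIDE_CHAINS: dict[str, tuple[str, ...]] = {
    "ALA": ("CB",),
    "ARG": ("CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"),
    "ASN": ("CB", "CG", "OD1", "ND2"),
    "ASP": ("CB", "CG", "OD1", "OD2"),
    "CYS": ("CB", "SG"),
    "GLN": ("CB", "CG", "CD", "OE1", "NE2"),
    "GLU": ("CB", "CG", "CD", "OE1", "OE2"),
    "GLY": (),
    "HIS": ("CB", "CG", "ND1", "CD2", "CE1", "NE2"),
    "ILE": ("CB", "CG1", "CG2", "CD1"),
    "LEU": ("CB", "CG", "CD1", "CD2"),
    "LYS": ("CB", "CG", "CD", "CE", "NZ"),
    "MET": ("CB", "CG", "SD", "CE"),
    "PHE": ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "PRO": ("CB", "CG", "CD"),
    "SER": ("CB", "OG"),
    "THR": ("CB", "OG1", "CG2"),
    "TRP": ("CB", "CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "TYR": ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"),
    "VAL": ("CB", "CG1", "CG2"),
}

RESIDUE_HEAVY_ATOMS: dict[str, frozenset[str]] = {
    name: frozenset(_BACKBONE + side) for name, side in _SIDE_CHAINS.items()
}

STANDARD_AMINO_ACIDS: frozenset[str] = frozenset(RESIDUE_HEAVY_ATOMS)

#: Residue names recognised as crystallographic / simulation water.
WATER_NAMES = frozenset({"HOH", "WAT", "DOD", "H2O", "SOL", "TIP", "TIP3", "SPC"})

#: Monoatomic ion residue names commonly deposited in the PDB.
ION_NAMES = frozenset(
    {
        "NA", "CL", "K", "MG", "CA", "ZN", "FE", "FE2", "MN", "CU", "CU1",
        "CO", "NI", "CD", "HG", "SR", "CS", "BR", "F", "IOD", "LI", "RB",
        "BA", "AL", "PB", "AG", "AU", "PT", "YB", "SM", "TL", "GA",
    }
)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ResidueId:
    """Author-style residue address: chain, sequence number, insertion code."""

    chain_id: str
    seq_num: int
    insertion_code: str = ""

    def __str__(self) -> str:  # e.g. "A:42" or "A:42A"
        return f"{self.chain_id}:{self.seq_num}{self.insertion_code}"


@dataclass
class AtomRecord:
    """One atom of a cleaned structure (coordinates in Angstrom)."""

    serial: int
    name: str
    element: str
    alt_loc: str
    occupancy: float
    b_factor: float
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise StructureError(f"atom {self.name!r}: coords must be 3 finite reals")
        if not self.name.strip():
            raise StructureError("atom name must be non-empty")

    @property
    def is_hydrogen(self) -> bool:
        return _is_hydrogen(self.name, self.element)


@dataclass
class Residue:
    id: ResidueId
    res_name: str
    atoms: list[AtomRecord]
    ca_index: int

    def __post_init__(self) -> None:
        if self.res_name not in STANDARD_AMINO_ACIDS:
            raise StructureError(f"{self.id}: {self.res_name!r} is not a standard amino acid")
        ca_positions = [i for i, a in enumerate(self.atoms) if a.name == "CA"]
        if len(ca_positions) != 1 or ca_positions[0] != self.ca_index:
            raise StructureError(f"{self.id}: residue must contain exactly one CA atom")

    @property
    def ca(self) -> AtomRecord:
        return self.atoms[self.ca_index]


@dataclass
class StructureModel:
    """An ordered list of validated residues (one conformer)."""

    residues: list[Residue]
    source_label: str = ""

    @property
    def atom_count(self) -> int:
        return sum(len(r.atoms) for r in self.residues)

    def iter_atoms(self) -> Iterable[tuple[int, Residue, AtomRecord]]:
        """Yield (flat atom index, residue, atom) in file order."""
        i = 0
        for res in self.residues:
            for atom in res.atoms:
                yield i, res, atom
                i += 1

    def coords(self) -> np.ndarray:
        """All atom coordinates as an (N, 3) array, in topology order."""
        return np.array([a.coords for _, _, a in self.iter_atoms()], dtype=float).reshape(-1, 3)

    def residue_atom_indices(self) -> list[np.ndarray]:
        """Per residue, the flat topology indices of its atoms."""
        out, i = [], 0
        for res in self.residues:
            out.append(np.arange(i, i + len(res.atoms)))
            i += len(res.atoms)
        return out

    def ca_coords(self) -> np.ndarray:
        return np.array([r.ca.coords for r in self.residues], dtype=float).reshape(-1, 3)


@dataclass
class ValidationReport:
    removed_nonprotein_chains: list[str] = field(default_factory=list)
    removed_hetero_records: dict[str, int] = field(
        default_factory=lambda: {"ligand": 0, "ion": 0, "water": 0}
    )
    rejected_residues: list[tuple[ResidueId, str]] = field(default_factory=list)
    format_anomalies: list[str] = field(default_factory=list)
    retained_residue_count: int = 0

    @property
    def is_clean(self) -> bool:
        return (
            not self.removed_nonprotein_chains
            and not self.rejected_residues
            and not self.format_anomalies
            and sum(self.removed_hetero_records.values()) == 0
        )


# ---------------------------------------------------------------------------
# Raw parsing
# ---------------------------------------------------------------------------


@dataclass
class RawAtom:
    """One ATOM/HETATM record, parsed but not yet validated."""

    category: str  # "ATOM" or "HETATM"
    serial: int
    name: str
    alt_loc: str
    res_name: str
    chain_id: str
    seq_num: int
    insertion_code: str
    coords: np.ndarray
    occupancy: float
    b_factor: float
    element: str

    @property
    def residue_id(self) -> ResidueId:
        return ResidueId(self.chain_id, self.seq_num, self.insertion_code)


@dataclass
class RawModel:
    label: str
    records: list[RawAtom] = field(default_factory=list)
    anomalies: list[str] = field(default_factory=list)


def _is_hydrogen(name: str, element: str) -> bool:
    el = element.strip().upper()
    if el:
        return el in ("H", "D")
    # No element column: infer from the atom name (PDB convention puts a
    # leading digit before H in names like "1HB1").
    stripped = name.strip().lstrip("0123456789")
    return stripped[:1].upper() in ("H", "D")


def _parse_atom_line(line: str, lineno: int, anomalies: list[str]) -> RawAtom | None:
    line = line.rstrip("\n").ljust(80)
    category = line[:6].strip()
    try:
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except ValueError:
        anomalies.append(f"line {lineno}: unparseable coordinates, record skipped")
        return None
    if not (math.isfinite(x) and math.isfinite(y) and math.isfinite(z)):
        anomalies.append(f"line {lineno}: non-finite coordinates, record skipped")
        return None
    name = line[12:16].strip()
    if not name:
        anomalies.append(f"line {lineno}: blank atom name, record skipped")
        return None
    try:
        serial = int(line[6:11])
    except ValueError:
        serial = -1
        anomalies.append(f"line {lineno}: unparseable atom serial")
    try:
        seq_num = int(line[22:26])
    except ValueError:
        anomalies.append(f"line {lineno}: unparseable residue number, record skipped")
        return None
    try:
        occupancy = float(line[54:60]) if line[54:60].strip() else 1.0
    except ValueError:
        occupancy = 1.0
        anomalies.append(f"line {lineno}: unparseable occupancy, defaulted to 1.0")
    try:
        b_factor = float(line[60:66]) if line[60:66].strip() else 0.0
    except ValueError:
        b_factor = 0.0
        anomalies.append(f"line {lineno}: unparseable B-factor, defaulted to 0.0")
    return RawAtom(
        category=category,
        serial=serial,
        name=name,
        alt_loc=line[16].strip(),
        res_name=line[17:20].strip(),
        chain_id=line[21].strip() or " ",
        seq_num=seq_num,
        insertion_code=line[26].strip(),
        coords=np.array([x, y, z]),
        occupancy=occupancy,
        b_factor=b_factor,
        element=line[76:78].strip(),
    )


def parse_pdb(stream: IO[str]) -> list[RawModel]:
    """Split a PDB text stream into raw models.

    Each MODEL/ENDMDL block yields one :class:`RawModel`; a file without
    MODEL records yields exactly one. ATOM and HETATM records are kept
    with their category tag; record order is preserved. Lines whose
    coordinate fields cannot be parsed are skipped and recorded as
    anomalies on their model.

    Raises
    ------
    StructureError
        If the stream contains no atom records at all.
    """
    models: list[RawModel] = []
    current: RawModel | None = None
    saw_model_record = False
    for lineno, line in enumerate(stream, start=1):
        rec = line[:6].strip()
        if rec == "MODEL":
            saw_model_record = True
            if current is not None and current.records:
                models.append(current)
            current = RawModel(label=line[6:].strip() or str(len(models) + 1))
        elif rec == "ENDMDL":
            if current is not None:
                models.append(current)
                current = None
        elif rec in ("ATOM", "HETATM"):
            if current is None:
                current = RawModel(label=str(len(models) + 1))
            atom = _parse_atom_line(line, lineno, current.anomalies)
            if atom is not None:
                current.records.append(atom)
    if current is not None and (current.records or current.anomalies):
        models.append(current)
    if not any(m.records for m in models):
        raise StructureError("no atom records found")
    if saw_model_record:
        models = [m for m in models if m.records]
    return models


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


def _hetero_category(res_name: str) -> str:
    if res_name in WATER_NAMES:
        return "water"
    if res_name in ION_NAMES:
        return "ion"
    return "ligand"


def _collapse_alt_locs(records: list[RawAtom], rid: ResidueId, anomalies: list[str]) -> list[RawAtom]:
    """Keep one record per atom name: highest occupancy, ties to first seen."""
    best: dict[str, RawAtom] = {}
    order: list[str] = []
    had_alt = False
    for rec in records:
        if rec.name not in best:
            best[rec.name] = rec
            order.append(rec.name)
        else:
            had_alt = True
            if rec.occupancy > best[rec.name].occupancy:
                best[rec.name] = rec
    if had_alt:
        anomalies.append(f"residue {rid}: alternate locations collapsed to highest occupancy")
    return [best[name] for name in order]


def validate_structure(raw: RawModel) -> tuple[StructureModel, ValidationReport]:
    """Clean one raw model into a :class:`StructureModel` plus a report.

    Cleaning rules: HETATM entities (ligands, ions, waters) are removed
    and counted by category; chains with no standard amino-acid residue
    are removed whole; alternate-location groups are collapsed to the
    highest-occupancy conformer; residues missing any heavy atom of
    their standard composition (hydrogens never required) are rejected.
    Coordinates are never modified.

    Raises
    ------
    StructureError
        If no valid protein residue survives.
    """
    report = ValidationReport(format_anomalies=list(raw.anomalies))

    # Group records into residues, preserving file order.
    groups: dict[tuple[str, int, str, str], list[RawAtom]] = {}
    group_order: list[tuple[str, int, str, str]] = []
    seen_ids: set[tuple[str, int, str]] = set()
    last_id: tuple[str, int, str] | None = None
    prev_serial: int | None = None
    for rec in raw.records:
        if prev_serial is not None and 0 <= rec.serial <= prev_serial:
            msg = "non-monotonic atom serial numbers"
            if msg not in report.format_anomalies:
                report.format_anomalies.append(msg)
        if rec.serial >= 0:
            prev_serial = rec.serial
        key = (rec.chain_id, rec.seq_num, rec.insertion_code, rec.res_name)
        rid3 = key[:3]
        if key not in groups:
            if rid3 in seen_ids and rid3 != last_id:
                report.format_anomalies.append(
                    f"duplicate residue id {ResidueId(*rid3)} (non-contiguous records)"
                )
            groups[key] = []
            group_order.append(key)
        seen_ids.add(rid3)
        last_id = rid3
        groups[key].append(rec)

    # Classify chains: protein iff >= 1 standard amino-acid ATOM residue.
    protein_chains = {
        chain
        for (chain, _, _, res_name), recs in groups.items()
        if res_name in STANDARD_AMINO_ACIDS and any(r.category == "ATOM" for r in recs)
    }
    all_chains_in_order: list[str] = []
    for chain, *_ in group_order:
        if chain not in all_chains_in_order:
            all_chains_in_order.append(chain)
    report.removed_nonprotein_chains = [c for c in all_chains_in_order if c not in protein_chains]

    residues: list[Residue] = []
    retained_ids: set[ResidueId] = set()
    for key in group_order:
        chain, seq_num, icode, res_name = key
        rid = ResidueId(chain, seq_num, icode)
        recs = groups[key]
        is_het = all(r.category == "HETATM" for r in recs)
        if is_het:
            report.removed_hetero_records[_hetero_category(res_name)] += len(recs)
            continue
        if res_name not in STANDARD_AMINO_ACIDS:
            # ATOM records with a non-standard residue name (e.g. MSE)
            report.rejected_residues.append((rid, f"nonstandard residue name {res_name}"))
            report.format_anomalies.append(
                f"residue {rid}: nonstandard residue name {res_name} treated as non-protein"
            )
            continue
        recs = _collapse_alt_locs(recs, rid, report.format_anomalies)
        heavy = {r.name for r in recs if not _is_hydrogen(r.name, r.element)}
        missing = RESIDUE_HEAVY_ATOMS[res_name] - heavy
        if missing:
            report.rejected_residues.append(
                (rid, "missing atoms: " + ",".join(sorted(missing)))
            )
            continue
        atoms = [
            AtomRecord(
                serial=r.serial,
                name=r.name,
                element=r.element,
                alt_loc="",
                occupancy=min(max(r.occupancy, 0.0), 1.0),
                b_factor=r.b_factor,
                coords=r.coords,
            )
            for r in recs
        ]
        ca_index = next(i for i, a in enumerate(atoms) if a.name == "CA")
        if rid in retained_ids:
            report.format_anomalies.append(f"duplicate residue id {rid}; later copy rejected")
            report.rejected_residues.append((rid, "duplicate residue id"))
            continue
        retained_ids.add(rid)
        residues.append(Residue(id=rid, res_name=res_name, atoms=atoms, ca_index=ca_index))

    if not residues:
        raise StructureError("no valid protein residues")
    report.retained_residue_count = len(residues)
    return StructureModel(residues=residues, source_label=raw.label), report


def read_structure(stream: IO[str]) -> tuple[StructureModel, ValidationReport]:
    """Parse and validate a single-structure PDB stream.

    Multi-model files (e.g. NMR entries) contribute only their first
    model; a note is added to the report's format anomalies.
    """
    models = parse_pdb(stream)
    model, report = validate_structure(models[0])
    if len(models) > 1:
        report.format_anomalies.append(
            f"input contains {len(models)} models; model 1 used as the structure"
        )
    return model, report


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

_ATOM_FMT = (
    "ATOM  {serial:>5d} {name:<4s}{alt:1s}{res_name:>3s} {chain:1s}"
    "{seq_num:>4d}{icode:1s}   {x:>8.3f}{y:>8.3f}{z:>8.3f}{occ:>6.2f}{b:>6.2f}"
    "          {element:>2s}\n"
)


def _format_atom_name(name: str, element: str) -> str:
    # PDB convention: 1-char element symbols start in column 14.
    if len(name) < 4 and len(element.strip()) < 2 and not name[:1].isdigit():
        return f" {name:<3s}"
    return f"{name:<4s}"


def format_atom_line(
    serial: int,
    atom: AtomRecord,
    res: Residue,
    coords: np.ndarray | None = None,
    b_factor: float | None = None,
) -> str:
    xyz = atom.coords if coords is None else np.asarray(coords, dtype=float)
    return _ATOM_FMT.format(
        serial=serial,
        name=_format_atom_name(atom.name, atom.element),
        alt="",
        res_name=res.res_name,
        chain=res.id.chain_id,
        seq_num=res.id.seq_num,
        icode=res.id.insertion_code or " ",
        x=xyz[0],
        y=xyz[1],
        z=xyz[2],
        occ=atom.occupancy,
        b=atom.b_factor if b_factor is None else b_factor,
        element=atom.element,
    )


def write_pdb(model: StructureModel, stream: IO[str]) -> None:
    """Write a cleaned structure as standard ATOM records (with TER/END)."""
    if not model.residues:
        raise StructureError("cannot write an empty model")
    serial = 0
    prev_chain: str | None = None
    for res in model.residues:
        if prev_chain is not None and res.id.chain_id != prev_chain:
            stream.write("TER\n")
        prev_chain = res.id.chain_id
        for atom in res.atoms:
            serial += 1
            stream.write(format_atom_line(serial, atom, res))
    stream.write("TER\nEND\n")


def write_validation_log(report: ValidationReport, stream: IO[str]) -> None:
    """Write the validation report as a human-readable plain-text log."""
    stream.write("Structure validation log\n")
    stream.write("========================\n")
    if report.is_clean:
        stream.write("no issues found\n")
    if report.removed_nonprotein_chains:
        stream.write(
            "Removed non-protein chains: "
            + ", ".join(report.removed_nonprotein_chains)
            + "\n"
        )
    for cat in ("ligand", "ion", "water"):
        n = report.removed_hetero_records.get(cat, 0)
        if n:
            stream.write(f"Removed {cat} records: {n}\n")
    for rid, reason in report.rejected_residues:
        stream.write(f"Rejected residue {rid}: {reason}\n")
    for msg in report.format_anomalies:
        stream.write(f"Anomaly: {msg}\n")
    stream.write(f"Retained residues: {report.retained_residue_count}\n")
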