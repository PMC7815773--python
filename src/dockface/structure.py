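"""Two-chain protein structures in PDB format.

Defines the atomic record, residue identity, and dimer-complex containers
that every downstream computation (SASA, contacts, FNAT/iRMSD, features)
consumes, plus fixed-column PDB reading/writing, atom filtering, and rigid
transforms.

Conventions: coordinates are Cartesian Angstroms exactly as printed in PDB
columns 31-54; residue identity is (chain_id, residue_seq, insertion_code)
with author numbering kept verbatim, because reference/decoy matching for
FNAT and iRMSD relies on identical residue keys. Only the first MODEL of a
multi-model file is read (a decoy is a single pose).
"""

from __future__ import annotations

import gzip
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "STANDARD_RESIDUES",
    "AtomRecord",
    "ResidueKey",
    "DimerComplex",
    "FilterPolicy",
    "PDBFormatError",
    "parse_pdb",
    "parse_pdb_file",
    "filter_atoms",
    "rigid_transform",
    "write_pdb",
    "coords_of",
]

#: The 20 standard amino-acid three-letter codes; the feature schema and all
#: interface statistics are defined over these types only.
STANDARD_RESIDUES: tuple[str, ...] = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)

_WATERS = {"HOH", "WAT", "DOD", "H2O"}


class PDBFormatError(ValueError):
    """Raised for unparseable or out-of-range PDB content."""


@dataclass(frozen=True, slots=True)
class ResidueKey:
    """Identity of one residue: chain, author seq number, insertion code, type.

    Ordering within a chain is (residue_seq, insertion_code) lexicographic.
    """

    chain_id: str
    residue_seq: int
    insertion_code: str
    residue_name: str

    def sort_key(self) -> tuple:
        return (self.chain_id, self.residue_seq, self.insertion_code)

    def swap_chain(self, mapping: dict[str, str]) -> "ResidueKey":
        return replace(self, chain_id=mapping.get(self.chain_id, self.chain_id))


@dataclass(slots=True)
class AtomRecord:
    """One heavy-atom (or, pre-filtering, any) ATOM/HETATM record."""

    serial: int
    atom_name: str
    element: str
    alt_loc: str
    residue_name: str
    chain_id: str
    residue_seq: int
    insertion_code: str
    x: float
    y: float
    z: float
    occupancy: float = 1.0
    het: bool = False

    @property
    def residue_key(self) -> ResidueKey:
        return ResidueKey(self.chain_id, self.residue_seq,
                          self.insertion_code, self.residue_name)

    @property
    def coord(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass(slots=True)
class DimerComplex:
    """Two labelled chains of atoms; the unit all computations consume."""

    receptor: list[AtomRecord]
    ligand: list[AtomRecord]
    label: str = ""

    def __post_init__(self) -> None:
        rc = {a.chain_id for a in self.receptor}
        lc = {a.chain_id for a in self.ligand}
        if len(rc) > 1 or len(lc) > 1:
            raise ValueError("each side of a dimer must be a single chain")
        if rc and lc and rc == lc:
            raise ValueError("receptor and ligand must have distinct chain ids")

    @property
    def receptor_chain_id(self) -> str:
        return self.receptor[0].chain_id if self.receptor else ""

    @property
    def ligand_chain_id(self) -> str:
        return self.ligand[0].chain_id if self.ligand else ""

    @property
    def atoms(self) -> list[AtomRecord]:
        return list(self.receptor) + list(self.ligand)

    def residue_keys(self) -> list[ResidueKey]:
        seen: dict[ResidueKey, None] = {}
        for a in self.atoms:
            seen.setdefault(a.residue_key)
        return list(seen)

    def with_atoms(self, receptor: list[AtomRecord], ligand: list[AtomRecord],
                   label: str | None = None) -> "DimerComplex":
        return DimerComplex(receptor, ligand,
                            self.label if label is None else label)


@dataclass(frozen=True, slots=True)
class FilterPolicy:
    """Atom-filtering policy applied before any computation.

    Hydrogens/deuteriums, HETATM records (waters included), non-standard
    residues and disfavoured alternate locations are removed. The default
    alt-loc rule keeps atoms with an empty altLoc or altLoc 'A', the most
    common PDB convention.
    """

    keep_alt_locs: tuple[str, ...] = ("", "A")
    drop_hydrogens: bool = True
    drop_hetero: bool = True
    standard_residues_only: bool = True


def coords_of(atoms: Sequence[AtomRecord]) -> np.ndarray:
    """Coordinates of a list of atoms as an (n, 3) float array."""
    if not atoms:
        return np.zeros((0, 3), dtype=float)
    return np.array([[a.x, a.y, a.z] for a in atoms], dtype=float)


# ---------------------------------------------------------------------------
# PDB fixed-column reading
# ---------------------------------------------------------------------------

def _infer_element(atom_name: str, residue_name: str) -> str:
    name = atom_name.strip()
    if not name:
        return ""
    # PDB names like "1HB2" or "HG21": digit-led or H-led names are hydrogens
    stripped = name.lstrip("0123456789")
    return stripped[0] if stripped else name[0]


def _parse_atom_line(line: str, lineno: int) -> AtomRecord:
    try:
        serial = int(line[6:11])
        atom_name = line[12:16].strip()
        alt_loc = line[16].strip()
        residue_name = line[17:20].strip()
        chain_id = line[21].strip()
        residue_seq = int(line[22:26])
        insertion_code = line[26].strip()
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        occ_field = line[54:60].strip()
        occupancy = float(occ_field) if occ_field else 1.0
        element = line[76:78].strip() if len(line) >= 78 else ""
    except (ValueError, IndexError) as exc:
        raise PDBFormatError(
            f"unparseable ATOM/HETATM record at line {lineno}: {line.rstrip()!r}"
        ) from exc
    if not atom_name:
        raise PDBFormatError(f"empty atom name at line {lineno}")
    if not (math.isfinite(x) and math.isfinite(y) and math.isfinite(z)):
        raise PDBFormatError(f"non-finite coordinate at line {lineno}")
    if not element:
        element = _infer_element(atom_name, residue_name)
    return AtomRecord(serial, atom_name, element, alt_loc, residue_name,
                      chain_id, residue_seq, insertion_code, x, y, z,
                      occupancy, het=line.startswith("HETATM"))


def parse_pdb(text: str, chain_ids: tuple[str, str] | None = None,
              label: str = "") -> DimerComplex:
    """Parse PDB text into a two-chain :class:`DimerComplex`.

    Atoms are kept in file order; only the first MODEL block is read.
    If ``chain_ids`` is given, exactly those two chains are extracted (in
    that receptor, ligand order); otherwise the first two distinct chain
    ids encountered are used.

    Raises :class:`PDBFormatError` on an unparseable ATOM line (with its
    line number), a missing requested chain, or fewer than two chains.
    """
    atoms: list[AtomRecord] = []
    in_later_model = False
    model_count = 0
    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6]
        if rec.startswith("MODEL"):
            model_count += 1
            if model_count > 1:
                in_later_model = True
        elif rec.startswith("ENDMDL"):
            if model_count >= 1:
                in_later_model = True
        elif rec in ("ATOM  ", "HETATM") and not in_later_model:
            atoms.append(_parse_atom_line(line, lineno))

    chains_present: list[str] = []
    for a in atoms:
        if a.chain_id not in chains_present:
            chains_present.append(a.chain_id)

    if chain_ids is not None:
        rec_id, lig_id = chain_ids
        for cid in (rec_id, lig_id):
            if cid not in chains_present:
                raise PDBFormatError(
                    f"requested chain {cid!r} not present "
                    f"(found {chains_present})")
    else:
        if len(chains_present) < 2:
            raise PDBFormatError(
                f"need two chains, found {chains_present or 'none'}")
        rec_id, lig_id = chains_present[0], chains_present[1]

    receptor = [a for a in atoms if a.chain_id == rec_id]
    ligand = [a for a in atoms if a.chain_id == lig_id]
    return DimerComplex(receptor, ligand, label)


def parse_pdb_file(path: str | Path,
                   chain_ids: tuple[str, str] | None = None) -> DimerComplex:
    """Parse a plain or gzip-compressed PDB file."""
    path = Path(path)
    if path.suffix == ".gz":
        with gzip.open(path, "rt") as fh:
            text = fh.read()
    else:
        text = path.read_text()
    return parse_pdb(text, chain_ids=chain_ids, label=path.stem)


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def _filter_chain(atoms: Iterable[AtomRecord],
                  policy: FilterPolicy) -> list[AtomRecord]:
    kept: list[AtomRecord] = []
    seen: set[tuple[ResidueKey, str]] = set()
    for a in atoms:
        if policy.drop_hetero and (a.het or a.residue_name in _WATERS):
            continue
        if policy.drop_hydrogens and a.element.upper() in ("H", "D"):
            continue
        if policy.standard_residues_only and \
                a.residue_name not in STANDARD_RESIDUES:
            continue
        if a.alt_loc not in policy.keep_alt_locs:
            continue
        key = (a.residue_key, a.atom_name)
        if key in seen:  # e.g. altLoc '' and 'A' copies of the same atom
            continue
        seen.add(key)
        kept.append(a)
    return kept


def filter_atoms(complex_: DimerComplex,
                 policy: FilterPolicy = FilterPolicy()) -> DimerComplex:
    """Apply the heavy-atom / standard-residue / alt-loc filter.

    Idempotent. A residue left with zero atoms simply disappears (a warning
    is emitted when an entire chain empties out).
    """
    receptor = _filter_chain(complex_.receptor, policy)
    ligand = _filter_chain(complex_.ligand, policy)
    for name, before, after in (("receptor", complex_.receptor, receptor),
                                ("ligand", complex_.ligand, ligand)):
        if before and not after:
            warnings.warn(f"{name} chain lost all atoms during filtering",
                          stacklevel=2)
    return complex_.with_atoms(receptor, ligand)


# ---------------------------------------------------------------------------
# Rigid transforms
# ---------------------------------------------------------------------------

def _check_rotation(rotation: np.ndarray, tol: float = 1e-6) -> np.ndarray:
    rotation = np.asarray(rotation, dtype=float)
    if rotation.shape != (3, 3):
        raise ValueError("rotation must be a 3x3 matrix")
    if not np.allclose(rotation.T @ rotation, np.eye(3), atol=tol):
        raise ValueError("rotation matrix is not orthonormal")
    if not math.isclose(float(np.linalg.det(rotation)), 1.0, abs_tol=tol):
        raise ValueError("rotation matrix determinant is not +1 "
                         "(improper rotation)")
    return rotation


def rigid_transform(atoms: Sequence[AtomRecord], rotation: np.ndarray,
                    translation: np.ndarray) -> list[AtomRecord]:
    """Map every coordinate x -> R @ x + t; all other fields are preserved.

    ``rotation`` must be orthonormal with determinant +1 (checked to 1e-6).
    """
    rotation = _check_rotation(rotation)
    translation = np.asarray(translation, dtype=float).reshape(3)
    xyz = coords_of(atoms) @ rotation.T + translation
    out = []
    for a, (x, y, z) in zip(atoms, xyz):
        out.append(replace(a, x=float(x), y=float(y), z=float(z)))
    return out


# ---------------------------------------------------------------------------
# PDB writing
# ---------------------------------------------------------------------------

def _format_atom_name(name: str, element: str) -> str:
    # Column alignment rule: element symbol occupies cols 13-14, so 1-3 char
    # names of single-letter elements start at col 14.
    if len(name) >= 4:
        return name[:4]
    if len(element) == 2:
        return f"{name:<4}"[:4]
    return f" {name:<3}"


def _format_atom_line(a: AtomRecord) -> str:
    for v in (a.x, a.y, a.z):
        if not (-999.999 <= v <= 9999.999):
            raise PDBFormatError(
                f"coordinate {v} exceeds the PDB fixed-width field")
    record = "HETATM" if a.het else "ATOM  "
    return (f"{record}{a.serial:>5} {_format_atom_name(a.atom_name, a.element)}"
            f"{a.alt_loc or ' '}{a.residue_name:>3} {a.chain_id or ' '}"
            f"{a.residue_seq:>4}{a.insertion_code or ' '}   "
            f"{a.x:8.3f}{a.y:8.3f}{a.z:8.3f}{a.occupancy:6.2f}{0.0:6.2f}"
            f"          {a.element:>2}")


def write_pdb(complex_: DimerComplex) -> str:
    """Serialize to fixed-column PDB text (one chain, TER, the other, END).

    Round-trips through :func:`parse_pdb`: all fields identical, coordinates
    to three decimals. Coordinates outside the +/-9999.999 field raise
    :class:`PDBFormatError`.
    """
    lines = [_format_atom_line(a) for a in complex_.receptor]
    lines.append("TER")
    lines.extend(_format_atom_line(a) for a in complex_.ligand)
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"
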