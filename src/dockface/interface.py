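"""Interface residues and cross-chain contacts, hydrogen bonds, salt bridges.

A residue-residue "contact" is any cross-chain heavy-atom pair within a
distance cutoff (5 A by default, the CAPRI convention used by FNAT).
Interface residues come in two flavours: a distance-based definition
(10 A, used to pick the residues entering iRMSD) and an area-based one
(buried surface area > 0.1 A^2, mirroring an area-based interface notion,
used for feature extraction).

Hydrogen bonds are detected between donor and acceptor heavy atoms only
(distance <= 3.5 A): the filtered structures carry no hydrogens, so no
angular term is possible. Salt bridges pair oppositely charged side-chain
atoms across the interface within 4 A. Both atom tables ship as editable
plain-text files.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Literal

import numpy as np
from scipy.spatial import cKDTree

from .structure import AtomRecord, DimerComplex, ResidueKey, coords_of
from . import sasa as _sasa

__all__ = [
    "ContactMap",
    "InterfaceDefinition",
    "BondRecord",
    "residue_contacts",
    "interface_residues",
    "hydrogen_bonds",
    "salt_bridges",
    "HBOND_DMAX",
    "SALT_BRIDGE_DMAX",
    "CONTACT_CUTOFF",
    "IRMSD_INTERFACE_CUTOFF",
    "BSA_INTERFACE_THRESHOLD",
]

CONTACT_CUTOFF = 5.0            # A, FNAT contact definition
IRMSD_INTERFACE_CUTOFF = 10.0   # A, interface-residue definition for iRMSD
BSA_INTERFACE_THRESHOLD = 0.1   # A^2, area-based interface definition
HBOND_DMAX = 3.5                # A, donor-to-acceptor heavy-atom distance
SALT_BRIDGE_DMAX = 4.0          # A, charged-atom pair distance


@dataclass(frozen=True, slots=True)
class ContactMap:
    """Cross-chain residue pairs (receptor key, ligand key) under a cutoff."""

    pairs: frozenset[tuple[ResidueKey, ResidueKey]]
    cutoff: float

    def __len__(self) -> int:
        return len(self.pairs)

    def transpose(self) -> "ContactMap":
        return ContactMap(frozenset((b, a) for a, b in self.pairs),
                          self.cutoff)


@dataclass(frozen=True, slots=True)
class InterfaceDefinition:
    """How 'interface residue' is decided: by distance or by buried area."""

    mode: Literal["contact_distance", "delta_asa"] = "contact_distance"
    cutoff: float = IRMSD_INTERFACE_CUTOFF   # A or A^2 depending on mode

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("interface cutoff must be positive")


@dataclass(frozen=True, slots=True)
class BondRecord:
    """One detected cross-chain hydrogen bond or salt bridge."""

    kind: Literal["hydrogen_bond", "salt_bridge"]
    donor_serial: int
    acceptor_serial: int
    residue_pair: tuple[str, str]   # unordered (sorted) 3-letter codes
    distance: float


def _cross_chain_atom_pairs(receptor: list[AtomRecord],
                            ligand: list[AtomRecord],
                            cutoff: float) -> list[tuple[int, int, float]]:
    """(receptor index, ligand index, distance) for all pairs within cutoff."""
    if not receptor or not ligand:
        return []
    rt = cKDTree(coords_of(receptor))
    lt = cKDTree(coords_of(ligand))
    dist = rt.sparse_distance_matrix(lt, cutoff, output_type="coo_matrix")
    return [(int(i), int(j), float(d))
            for i, j, d in zip(dist.row, dist.col, dist.data)]


def residue_contacts(dimer: DimerComplex,
                     cutoff: float = CONTACT_CUTOFF) -> ContactMap:
    """Residue pairs with any cross-chain heavy-atom pair within ``cutoff``."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    pairs = {
        (dimer.receptor[i].residue_key, dimer.ligand[j].residue_key)
        for i, j, _ in _cross_chain_atom_pairs(dimer.receptor, dimer.ligand,
                                               cutoff)
    }
    return ContactMap(frozenset(pairs), cutoff)


def interface_residues(
    dimer: DimerComplex,
    definition: InterfaceDefinition = InterfaceDefinition(),
    sasa_params: dict | None = None,
) -> tuple[set[ResidueKey], set[ResidueKey]]:
    """Interface residue sets (receptor side, ligand side).

    ``contact_distance`` mode selects residues with any heavy atom within
    the cutoff of the other chain; ``delta_asa`` mode selects residues whose
    buried surface area exceeds the threshold (``sasa_params`` may pass
    probe / n_points / radii through to the SASA engine).
    """
    if definition.mode == "contact_distance":
        rset: set[ResidueKey] = set()
        lset: set[ResidueKey] = set()
        for i, j, _ in _cross_chain_atom_pairs(dimer.receptor, dimer.ligand,
                                               definition.cutoff):
            rset.add(dimer.receptor[i].residue_key)
            lset.add(dimer.ligand[j].residue_key)
        return rset, lset
    if definition.mode == "delta_asa":
        bsa = _sasa.delta_asa(dimer, **(sasa_params or {}))
        rc = dimer.receptor_chain_id
        selected = {k for k, v in bsa.items() if v > definition.cutoff}
        return ({k for k in selected if k.chain_id == rc},
                {k for k in selected if k.chain_id != rc})
    raise ValueError(f"unknown interface mode {definition.mode!r}")


# ---------------------------------------------------------------------------
# Donor / acceptor / charged-atom tables
# ---------------------------------------------------------------------------

def _load_hbond_tables() -> tuple[set[tuple[str, str]], set[tuple[str, str]]]:
    donors: set[tuple[str, str]] = set()
    acceptors: set[tuple[str, str]] = set()
    text = resources.files("dockface.data").joinpath("hbond_atoms.txt") \
        .read_text()
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        role, res, atom = line.split()
        (donors if role == "donor" else acceptors).add((res, atom))
    return donors, acceptors


def _load_charged_table() -> tuple[set[tuple[str, str]], set[tuple[str, str]]]:
    pos: set[tuple[str, str]] = set()
    neg: set[tuple[str, str]] = set()
    text = resources.files("dockface.data").joinpath("charged_atoms.txt") \
        .read_text()
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        sign, res, atom = line.split()
        (pos if sign == "+" else neg).add((res, atom))
    return pos, neg


_HBOND_TABLES: tuple[set, set] | None = None
_CHARGED_TABLES: tuple[set, set] | None = None


def _hbond_tables() -> tuple[set[tuple[str, str]], set[tuple[str, str]]]:
    global _HBOND_TABLES
    if _HBOND_TABLES is None:
        _HBOND_TABLES = _load_hbond_tables()
    return _HBOND_TABLES


def _charged_tables() -> tuple[set[tuple[str, str]], set[tuple[str, str]]]:
    global _CHARGED_TABLES
    if _CHARGED_TABLES is None:
        _CHARGED_TABLES = _load_charged_table()
    return _CHARGED_TABLES


def _matches(table: set[tuple[str, str]], atom: AtomRecord) -> bool:
    return ((atom.residue_name, atom.atom_name) in table
            or ("*", atom.atom_name) in table)


def hydrogen_bonds(dimer: DimerComplex,
                   d_max: float = HBOND_DMAX) -> list[BondRecord]:
    """Cross-chain donor-to-acceptor heavy-atom pairs within ``d_max``.

    Donors and acceptors on either chain; each record carries the unordered
    residue-type pair (e.g. ('ARG', 'ASP')) used by the per-pair feature.
    """
    donors, acceptors = _hbond_tables()
    bonds: list[BondRecord] = []
    for i, j, d in _cross_chain_atom_pairs(dimer.receptor, dimer.ligand,
                                           d_max):
        ra, la = dimer.receptor[i], dimer.ligand[j]
        for donor, acceptor in ((ra, la), (la, ra)):
            if _matches(donors, donor) and _matches(acceptors, acceptor):
                pair = tuple(sorted((ra.residue_name, la.residue_name)))
                bonds.append(BondRecord("hydrogen_bond", donor.serial,
                                        acceptor.serial, pair, d))
                break  # one bond per atom pair even if both orientations fit
    return bonds


def salt_bridges(dimer: DimerComplex,
                 d_max: float = SALT_BRIDGE_DMAX) -> list[BondRecord]:
    """Oppositely charged side-chain atom pairs across chains within ``d_max``."""
    pos, neg = _charged_tables()
    bridges: list[BondRecord] = []
    for i, j, d in _cross_chain_atom_pairs(dimer.receptor, dimer.ligand,
                                           d_max):
        ra, la = dimer.receptor[i], dimer.ligand[j]
        opposite = ((_matches(pos, ra) and _matches(neg, la))
                    or (_matches(neg, ra) and _matches(pos, la)))
        if opposite:
            pair = tuple(sorted((ra.residue_name, la.residue_name)))
            bridges.append(BondRecord("salt_bridge", ra.serial, la.serial,
                                      pair, d))
    return bridges
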