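"""CAPRI-style decoy quality metrics: FNAT and interface RMSD.

FNAT is the fraction of the reference complex's cross-chain residue
contacts (any heavy-atom pair within 5 A) that are reproduced in a docked
model; 1.0 means the model's interface contains every native contact.

iRMSD superposes the backbone atoms (N, CA, C, O) of the interface
residues — defined on the REFERENCE complex only, at a 10 A heavy-atom
cutoff, so that all decoys are measured against the same residue set —
pooled over both chains, and reports the minimised RMSD.

For homodimers the two chain labels are arbitrary: when the two chains
share an identical residue sequence/numbering, both chain assignments are
evaluated and the more favourable one (max FNAT, min iRMSD) is reported.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .structure import AtomRecord, DimerComplex, ResidueKey, coords_of
from .interface import (CONTACT_CUTOFF, IRMSD_INTERFACE_CUTOFF,
                        InterfaceDefinition, interface_residues,
                        residue_contacts)

__all__ = [
    "SuperpositionResult",
    "DecoyScorer",
    "DecoyQuality",
    "kabsch",
    "fnat",
    "irmsd",
    "score_decoy",
    "BACKBONE_ATOMS",
]

logger = logging.getLogger(__name__)

BACKBONE_ATOMS = ("N", "CA", "C", "O")


@dataclass(frozen=True, slots=True)
class SuperpositionResult:
    """Optimal rigid superposition of one point set onto another."""

    rotation: np.ndarray    # 3x3, proper
    translation: np.ndarray  # 3-vector
    rmsd: float
    n_atoms: int


@dataclass(frozen=True, slots=True)
class DecoyQuality:
    """FNAT and iRMSD of one pose against its reference complex."""

    fnat: float
    irmsd: float
    n_native_contacts: int
    n_interface_residues: int


def kabsch(P: np.ndarray, Q: np.ndarray) -> SuperpositionResult:
    """Least-squares superposition of ``Q`` onto ``P`` (row-matched points).

    Returns the proper rotation R and translation t minimising
    ``RMSD(P, Q @ R.T + t)``; a reflection in the SVD solution is corrected
    by flipping the smallest singular direction, so R always has det +1.
    Degenerate (e.g. collinear) sets still return a minimising transform.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("P and Q must be matching Nx3 arrays")
    n = P.shape[0]
    if n < 3:
        raise ValueError("at least 3 matched atoms are required")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    H = Q0.T @ P0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = pc - R @ qc
    moved = Q @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - P) ** 2, axis=1))))
    return SuperpositionResult(R, t, rmsd, n)


def _chains_swappable(reference: DimerComplex) -> bool:
    """True when receptor and ligand share residue numbering and types."""
    def sig(atoms: list[AtomRecord]) -> list[tuple]:
        return [(a.residue_seq, a.insertion_code, a.residue_name, a.atom_name)
                for a in atoms]
    return sig(reference.receptor) == sig(reference.ligand)


def _swapped(model: DimerComplex) -> DimerComplex:
    """The same pose with receptor/ligand roles exchanged and ids relabelled."""
    from dataclasses import replace
    rc, lc = model.receptor_chain_id, model.ligand_chain_id
    new_receptor = [replace(a, chain_id=rc) for a in model.ligand]
    new_ligand = [replace(a, chain_id=lc) for a in model.receptor]
    return DimerComplex(new_receptor, new_ligand, model.label)


def _fnat_one(reference: DimerComplex, model: DimerComplex,
              cutoff: float) -> tuple[float, int]:
    ref_contacts = residue_contacts(reference, cutoff)
    if len(ref_contacts) == 0:
        raise ValueError("reference complex has no interface "
                         "(zero cross-chain contacts)")
    model_contacts = residue_contacts(model, cutoff)
    conserved = ref_contacts.pairs & model_contacts.pairs
    return len(conserved) / len(ref_contacts), len(ref_contacts)


def fnat(reference: DimerComplex, model: DimerComplex,
         cutoff: float = CONTACT_CUTOFF,
         allow_chain_swap: bool = True) -> float:
    """Fraction of the reference's native contacts conserved in ``model``.

    Contacts intersect by residue-key pair identity, so model residues
    missing from the reference (or vice versa) simply count as unconserved.
    For homodimers both chain assignments are tried and the larger fraction
    returned.
    """
    value, _ = _fnat_one(reference, model, cutoff)
    if allow_chain_swap and _chains_swappable(reference):
        swapped_value, _ = _fnat_one(reference, _swapped(model), cutoff)
        value = max(value, swapped_value)
    return value


def _interface_backbone(reference: DimerComplex, model: DimerComplex,
                        interface_cutoff: float,
                        atoms: tuple[str, ...]) -> tuple[np.ndarray, np.ndarray]:
    rset, lset = interface_residues(
        reference, InterfaceDefinition("contact_distance", interface_cutoff))
    selected = rset | lset
    if not selected:
        raise ValueError("reference complex has an empty interface at "
                         f"{interface_cutoff} A")
    ref_index: dict[tuple[ResidueKey, str], AtomRecord] = {
        (a.residue_key, a.atom_name): a
        for a in reference.atoms
        if a.residue_key in selected and a.atom_name in atoms
    }
    model_index = {(a.residue_key, a.atom_name): a for a in model.atoms}
    ref_pts, mod_pts = [], []
    missing = 0
    for key, ra in ref_index.items():
        ma = model_index.get(key)
        if ma is None:
            missing += 1
            continue
        ref_pts.append([ra.x, ra.y, ra.z])
        mod_pts.append([ma.x, ma.y, ma.z])
    if missing:
        logger.info("iRMSD: %d interface backbone atoms missing from the "
                    "model were dropped pairwise", missing)
    if len(ref_pts) < 3:
        raise ValueError("fewer than 3 matched interface backbone atoms")
    return np.array(ref_pts), np.array(mod_pts)


def irmsd(reference: DimerComplex, model: DimerComplex,
          interface_cutoff: float = IRMSD_INTERFACE_CUTOFF,
          atoms: tuple[str, ...] = BACKBONE_ATOMS,
          allow_chain_swap: bool = True) -> float:
    """Interface RMSD (A) after optimal superposition of the pooled interface.

    Interface residues are taken from the reference only; backbone atoms of
    those residues in both chains and both structures are matched by
    (residue key, atom name), Kabsch-superposed as one pooled set, and the
    minimised RMSD returned. For homodimers the better chain assignment is
    reported.
    """
    P, Q = _interface_backbone(reference, model, interface_cutoff, atoms)
    value = kabsch(P, Q).rmsd
    if allow_chain_swap and _chains_swappable(reference):
        Ps, Qs = _interface_backbone(reference, _swapped(model),
                                     interface_cutoff, atoms)
        value = min(value, kabsch(Ps, Qs).rmsd)
    return value


class DecoyScorer:
    """FNAT + iRMSD scoring with the reference-side work done once.

    Useful when many poses are scored against the same reference (decoy
    generation, batch evaluation); results are identical to calling
    :func:`fnat` and :func:`irmsd` pose by pose.
    """

    def __init__(self, reference: DimerComplex,
                 contact_cutoff: float = CONTACT_CUTOFF,
                 interface_cutoff: float = IRMSD_INTERFACE_CUTOFF,
                 atoms: tuple[str, ...] = BACKBONE_ATOMS,
                 allow_chain_swap: bool = True) -> None:
        self.reference = reference
        self.contact_cutoff = contact_cutoff
        self.interface_cutoff = interface_cutoff
        self.atoms = atoms
        self.ref_contacts = residue_contacts(reference, contact_cutoff)
        if len(self.ref_contacts) == 0:
            raise ValueError("reference complex has no interface "
                             "(zero cross-chain contacts)")
        rset, lset = interface_residues(
            reference,
            InterfaceDefinition("contact_distance", interface_cutoff))
        self.n_interface_residues = len(rset) + len(lset)
        self.swappable = allow_chain_swap and _chains_swappable(reference)

    def score(self, model: DimerComplex) -> DecoyQuality:
        models = [model] + ([_swapped(model)] if self.swappable else [])
        best_fnat, best_irmsd = 0.0, math.inf
        for m in models:
            conserved = self.ref_contacts.pairs & \
                residue_contacts(m, self.contact_cutoff).pairs
            best_fnat = max(best_fnat,
                            len(conserved) / len(self.ref_contacts))
            P, Q = _interface_backbone(self.reference, m,
                                       self.interface_cutoff, self.atoms)
            best_irmsd = min(best_irmsd, kabsch(P, Q).rmsd)
        return DecoyQuality(best_fnat, best_irmsd, len(self.ref_contacts),
                            self.n_interface_residues)


def score_decoy(reference: DimerComplex, model: DimerComplex,
                contact_cutoff: float = CONTACT_CUTOFF,
                interface_cutoff: float = IRMSD_INTERFACE_CUTOFF) -> DecoyQuality:
    """FNAT and iRMSD of one pose, bundled as a :class:`DecoyQuality`."""
    return DecoyScorer(reference, contact_cutoff,
                       interface_cutoff).score(model)
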