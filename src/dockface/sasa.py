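"""Solvent-accessible surface area and the desolvation energy surrogate.

Shrake-Rupley numerical SASA with a deterministic golden-spiral quadrature,
per-residue ASA, buried surface area (BSA) on complex formation, and an
atomic-solvation-parameter estimate of the interface binding energy dG.

Because the quadrature is deterministic and the identical point set, radii
and probe are used for the bound and unbound evaluations, each atom's
exposed-point count can only drop when the partner chain is added, so
BSA >= 0 holds exactly, not just statistically.

The dG surrogate is an Eisenberg-McLachlan-style desolvation sum
``dG = -sum_atoms sigma(class) * dASA`` (kcal/mol; more negative = more
stable interface). It is a rank/sign-faithful stand-in for a full interface
thermodynamics pipeline, not a calibrated binding free energy.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .structure import AtomRecord, DimerComplex, ResidueKey, coords_of

__all__ = [
    "RadiiTable",
    "SasaResult",
    "SolvationParams",
    "sphere_points",
    "compute_sasa",
    "per_residue_asa",
    "delta_asa",
    "atom_delta_asa",
    "solvation_delta_g",
    "atom_solvation_class",
]

DEFAULT_PROBE = 1.4      # water-probe radius, Angstrom
DEFAULT_N_POINTS = 960   # quadrature points per atom


def _data_text(name: str) -> str:
    return resources.files("dockface.data").joinpath(name).read_text()


@dataclass(frozen=True)
class RadiiTable:
    """Van der Waals radii: (residue, atom) entries with element fallback."""

    by_atom: Mapping[tuple[str, str], float]
    by_element: Mapping[str, float]
    default: float = 1.80

    def __post_init__(self) -> None:
        for r in (*self.by_atom.values(), *self.by_element.values(),
                  self.default):
            if not 0.5 < r < 3.0:
                raise ValueError(f"radius {r} outside the plausible "
                                 "(0.5, 3.0) Angstrom range")

    @classmethod
    def load(cls, text: str | None = None) -> "RadiiTable":
        """Parse the shipped (or a user-edited) plain-text radii table."""
        if text is None:
            text = _data_text("radii.txt")
        by_atom: dict[tuple[str, str], float] = {}
        by_element: dict[str, float] = {}
        default = 1.80
        for line in text.splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if parts[0] == "element":
                by_element[parts[1]] = float(parts[2])
            elif parts[0] == "atom":
                by_atom[(parts[1], parts[2])] = float(parts[3])
            elif parts[0] == "default":
                default = float(parts[1])
        return cls(by_atom, by_element, default)

    def radius(self, atom: AtomRecord) -> float:
        for key in ((atom.residue_name, atom.atom_name),
                    ("*", atom.atom_name)):
            if key in self.by_atom:
                return self.by_atom[key]
        elem = atom.element.upper() or atom.atom_name[:1]
        if elem in self.by_element:
            return self.by_element[elem]
        warnings.warn(f"no radius for {atom.residue_name}/{atom.atom_name} "
                      f"(element {elem!r}); using default {self.default} A",
                      stacklevel=3)
        return self.default


_DEFAULT_RADII: RadiiTable | None = None


def default_radii() -> RadiiTable:
    global _DEFAULT_RADII
    if _DEFAULT_RADII is None:
        _DEFAULT_RADII = RadiiTable.load()
    return _DEFAULT_RADII


@dataclass(slots=True)
class SasaResult:
    """Per-atom and per-residue accessible areas (A^2) plus the parameters used."""

    atom_area: np.ndarray
    residue_area: dict[ResidueKey, float]
    total: float
    probe: float
    n_points: int


def sphere_points(n: int) -> np.ndarray:
    """``n`` near-uniform unit vectors from the deterministic golden spiral.

    Identical output for identical ``n``; no randomness.
    """
    if n <= 0:
        raise ValueError("n must be a positive integer")
    i = np.arange(n, dtype=float)
    z = 1.0 - 2.0 * (i + 0.5) / n
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    golden_angle = math.pi * (3.0 - math.sqrt(5.0))
    theta = golden_angle * i
    return np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])


def _exposed_counts_numpy(xyz: np.ndarray, expanded: np.ndarray,
                          unit: np.ndarray,
                          neighbours: list[list[int]]) -> np.ndarray:
    n_points = unit.shape[0]
    counts = np.empty(len(xyz), dtype=np.int64)
    for i in range(len(xyz)):
        cand = np.array([j for j in neighbours[i] if j != i], dtype=int)
        if cand.size:
            sep2 = np.sum((xyz[cand] - xyz[i]) ** 2, axis=1)
            cut = expanded[i] + expanded[cand]
            cand = cand[sep2 < cut * cut]
        if cand.size == 0:
            counts[i] = n_points
            continue
        # closest occluders first: buried atoms run out of live points fast
        order = np.argsort(np.sum((xyz[cand] - xyz[i]) ** 2, axis=1))
        cand = cand[order]
        alive = xyz[i] + expanded[i] * unit
        for j in cand:
            d2 = np.sum((alive - xyz[j]) ** 2, axis=1)
            alive = alive[d2 >= expanded[j] ** 2]
            if alive.shape[0] == 0:
                break
        counts[i] = alive.shape[0]
    return counts


try:  # compiled kernel; the numpy path above is the behavioural reference
    from numba import njit

    @njit(cache=False)
    def _exposed_counts_jit(xyz, expanded, unit, nbr_flat, nbr_off):  # pragma: no cover - exercised via compute_sasa
        n_atoms = xyz.shape[0]
        n_points = unit.shape[0]
        counts = np.empty(n_atoms, dtype=np.int64)
        for i in range(n_atoms):
            n_exposed = 0
            for p in range(n_points):
                px = xyz[i, 0] + expanded[i] * unit[p, 0]
                py = xyz[i, 1] + expanded[i] * unit[p, 1]
                pz = xyz[i, 2] + expanded[i] * unit[p, 2]
                ok = True
                for k in range(nbr_off[i], nbr_off[i + 1]):
                    j = nbr_flat[k]
                    dx = px - xyz[j, 0]
                    dy = py - xyz[j, 1]
                    dz = pz - xyz[j, 2]
                    if dx * dx + dy * dy + dz * dz < expanded[j] ** 2:
                        ok = False
                        break
                if ok:
                    n_exposed += 1
            counts[i] = n_exposed
        return counts

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def _exposed_counts(xyz: np.ndarray, expanded: np.ndarray, unit: np.ndarray,
                    neighbours: list[list[int]]) -> np.ndarray:
    if not _HAVE_NUMBA:
        return _exposed_counts_numpy(xyz, expanded, unit, neighbours)
    # flatten ragged neighbour lists, pre-pruned to true occluders sorted
    # nearest-first (earlier break inside the kernel)
    flat: list[int] = []
    offsets = np.zeros(len(xyz) + 1, dtype=np.int64)
    for i in range(len(xyz)):
        cand = np.array([j for j in neighbours[i] if j != i], dtype=int)
        if cand.size:
            sep2 = np.sum((xyz[cand] - xyz[i]) ** 2, axis=1)
            cut = expanded[i] + expanded[cand]
            keep = sep2 < cut * cut
            cand, sep2 = cand[keep], sep2[keep]
            cand = cand[np.argsort(sep2)]
        flat.extend(cand.tolist())
        offsets[i + 1] = len(flat)
    return _exposed_counts_jit(xyz, expanded, unit,
                               np.array(flat, dtype=np.int64), offsets)


def compute_sasa(atoms: Sequence[AtomRecord],
                 radii: RadiiTable | None = None,
                 probe: float = DEFAULT_PROBE,
                 n_points: int = DEFAULT_N_POINTS) -> SasaResult:
    """Shrake-Rupley SASA of an atom set.

    Per-atom area = (exposed points / n_points) * 4 pi (r_i + probe)^2, a
    test point being exposed when it lies outside every neighbour's expanded
    sphere. Neighbour search is restricted to atoms within
    r_i + r_j + 2 probe via a k-d tree.
    """
    if len(atoms) == 0:
        raise ValueError("compute_sasa needs at least one atom")
    radii = radii or default_radii()
    xyz = coords_of(atoms)
    r = np.array([radii.radius(a) for a in atoms], dtype=float)
    expanded = r + probe
    unit = sphere_points(n_points)

    tree = cKDTree(xyz)
    max_reach = 2.0 * float(expanded.max())
    neighbours = tree.query_ball_tree(tree, max_reach)

    counts = _exposed_counts(xyz, expanded, unit, neighbours)
    areas = counts / n_points * 4.0 * math.pi * expanded ** 2

    residue_area: dict[ResidueKey, float] = {}
    for a, area in zip(atoms, areas):
        key = a.residue_key
        residue_area[key] = residue_area.get(key, 0.0) + float(area)
    return SasaResult(areas, residue_area, float(areas.sum()), probe, n_points)


def per_residue_asa(result: SasaResult) -> dict[ResidueKey, float]:
    """Residue area = sum of its atoms' areas; partitions the total."""
    return dict(result.residue_area)


def atom_delta_asa(dimer: DimerComplex,
                   radii: RadiiTable | None = None,
                   probe: float = DEFAULT_PROBE,
                   n_points: int = DEFAULT_N_POINTS,
                   ) -> tuple[np.ndarray, SasaResult, SasaResult, SasaResult]:
    """Per-atom area buried on complex formation, in ``dimer.atoms`` order.

    Returns (per-atom dASA, SASA of the complex, of the receptor alone, of
    the ligand alone). Same quadrature in all evaluations, so dASA >= 0
    exactly.
    """
    radii = radii or default_radii()
    bound = compute_sasa(dimer.atoms, radii, probe, n_points)
    free_r = compute_sasa(dimer.receptor, radii, probe, n_points)
    free_l = compute_sasa(dimer.ligand, radii, probe, n_points)
    free = np.concatenate([free_r.atom_area, free_l.atom_area])
    return free - bound.atom_area, bound, free_r, free_l


def delta_asa(dimer: DimerComplex,
              radii: RadiiTable | None = None,
              probe: float = DEFAULT_PROBE,
              n_points: int = DEFAULT_N_POINTS) -> dict[ResidueKey, float]:
    """Buried surface area per residue: ASA(chain alone) - ASA(complex) >= 0."""
    datom, _, _, _ = atom_delta_asa(dimer, radii, probe, n_points)
    out: dict[ResidueKey, float] = {}
    for a, d in zip(dimer.atoms, datom):
        key = a.residue_key
        out[key] = out.get(key, 0.0) + float(d)
    return out


# ---------------------------------------------------------------------------
# Desolvation energy surrogate
# ---------------------------------------------------------------------------

_CHARGED_O = {("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2")}
_CHARGED_N = {("LYS", "NZ"), ("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2"),
              ("HIS", "ND1"), ("HIS", "NE2")}


def atom_solvation_class(atom: AtomRecord) -> str:
    """Map an atom to one of the solvation classes C, N, O, S, O-, N+."""
    key = (atom.residue_name, atom.atom_name)
    if key in _CHARGED_O or atom.atom_name == "OXT":
        return "O-"
    if key in _CHARGED_N:
        return "N+"
    elem = atom.element.upper() or atom.atom_name[:1]
    if elem in ("C", "N", "O", "S"):
        return elem
    return "C"


@dataclass(frozen=True)
class SolvationParams:
    """Atomic solvation parameters sigma (kcal/mol/A^2) per atom class."""

    sigma: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.sigma.get("C", 0.0) <= 0.0:
            raise ValueError("carbon solvation parameter must be positive "
                             "(hydrophobic burial is stabilising)")

    @classmethod
    def load(cls, text: str | None = None) -> "SolvationParams":
        if text is None:
            text = _data_text("solvation.txt")
        sigma: dict[str, float] = {}
        for line in text.splitlines():
            line = line.split("#", 1)[0].strip()
            if line:
                cls_name, value = line.split()
                sigma[cls_name] = float(value)
        return cls(sigma)


_DEFAULT_SOLVATION: SolvationParams | None = None


def default_solvation() -> SolvationParams:
    global _DEFAULT_SOLVATION
    if _DEFAULT_SOLVATION is None:
        _DEFAULT_SOLVATION = SolvationParams.load()
    return _DEFAULT_SOLVATION


def solvation_delta_g(dimer: DimerComplex,
                      params: SolvationParams | None = None,
                      radii: RadiiTable | None = None,
                      probe: float = DEFAULT_PROBE,
                      n_points: int = DEFAULT_N_POINTS,
                      precomputed_delta: np.ndarray | None = None) -> float:
    """Interface stability estimate dG = -sum sigma(class) * dASA (kcal/mol).

    Exactly 0 when no area is buried; more negative = more stable, i.e.
    burying apolar carbon is favourable and burying charged groups is
    penalised. ``precomputed_delta`` lets callers reuse a per-atom dASA
    vector from :func:`atom_delta_asa`.
    """
    params = params or default_solvation()
    if precomputed_delta is None:
        precomputed_delta, _, _, _ = atom_delta_asa(dimer, radii, probe,
                                                    n_points)
    total = 0.0
    for atom, dasa in zip(dimer.atoms, precomputed_delta):
        total -= params.sigma[atom_solvation_class(atom)] * float(dasa)
    return total
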