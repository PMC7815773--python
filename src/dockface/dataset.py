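"""Decoy categorization, 1:5 training-set assembly, and synthetic data.

Categorization bands
--------------------
A pose is *native-like* when FNAT > 0.8 (FNAT scheme) or iRMSD < 5 A
(iRMSD scheme). Non-native-like poses are drawn from one of four bands
measuring how distinguishable they are from the natives:

==========  =================  ===================
band        FNAT interval      iRMSD interval (A)
==========  =================  ===================
high        [0, 0.25]          [15, inf)
moderate    (0.25, 0.5]        [10, 15)
weak        (0.5, 0.8]         [5, 10)
mixed       [0, 0.8]           [5, inf)
==========  =================  ===================

Upper boundaries are half-open against the next band so the three narrow
bands partition the non-native range exactly; a pose falling in neither
the native region nor the requested band is *excluded*.

Training sets keep a fixed 1:5 class ratio per reference complex: 2
natives (the reference itself plus the best-by-metric qualifying decoy)
and 10 non-natives sampled uniformly (seeded) from the band.

Synthetic data
--------------
``make_toy_dimer`` builds two compact random-walk chains with idealised
backbone geometry (N, CA, C, O, CB; 3.8 A consecutive CA-CA distance) and
docks them so at least 20% of residues are interfacial. Residue types are
drawn from a distribution enriched for types common at real interfaces
(ARG, ASP, GLU, PHE, TYR, ILE). ``generate_decoys`` emulates rigid-body
docking output: seeded random rotations (0-180 deg) and translations
(0-25 A) of the ligand, clash-rejected, each pose scored with FNAT and
iRMSD; a stratified mode keeps sampling until every band has a quota.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .structure import (AtomRecord, DimerComplex, coords_of,
                        rigid_transform)
from .interface import InterfaceDefinition, interface_residues, residue_contacts
from .metrics import DecoyQuality, DecoyScorer
from .features import FeatureVector, extract_features

__all__ = [
    "CategoryScheme",
    "DecoyRecord",
    "LabeledSet",
    "categorize",
    "assemble_examples",
    "build_band_datasets",
    "make_toy_dimer",
    "generate_decoys",
    "FNAT_BANDS",
    "IRMSD_BANDS",
]

NATIVE_FNAT_CUTOFF = 0.8
NATIVE_IRMSD_CUTOFF = 5.0

# band -> (low, high, low_closed, high_closed)
FNAT_BANDS: dict[str, tuple[float, float, bool, bool]] = {
    "high": (0.0, 0.25, True, True),
    "moderate": (0.25, 0.5, False, True),
    "weak": (0.5, 0.8, False, True),
    "mixed": (0.0, 0.8, True, True),
}
IRMSD_BANDS: dict[str, tuple[float, float, bool, bool]] = {
    "high": (15.0, math.inf, True, False),
    "moderate": (10.0, 15.0, True, False),
    "weak": (5.0, 10.0, True, False),
    "mixed": (5.0, math.inf, True, False),
}


@dataclass(frozen=True, slots=True)
class CategoryScheme:
    """Which metric defines the classes and which non-native band is used."""

    metric: Literal["fnat", "irmsd"] = "fnat"
    band: Literal["high", "moderate", "weak", "mixed"] = "high"

    def __post_init__(self) -> None:
        if self.metric not in ("fnat", "irmsd"):
            raise ValueError(f"unknown metric {self.metric!r}")
        if self.band not in FNAT_BANDS:
            raise ValueError(f"unknown band {self.band!r}")

    @property
    def interval(self) -> tuple[float, float, bool, bool]:
        table = FNAT_BANDS if self.metric == "fnat" else IRMSD_BANDS
        return table[self.band]

    def metric_value(self, quality: DecoyQuality) -> float:
        return quality.fnat if self.metric == "fnat" else quality.irmsd


def _in_interval(x: float, interval: tuple[float, float, bool, bool]) -> bool:
    low, high, lc, hc = interval
    above = x >= low if lc else x > low
    below = x <= high if hc else x < high
    return above and below


def categorize(quality: DecoyQuality, scheme: CategoryScheme) -> str:
    """Class label of one scored pose: 'native', 'non_native' or 'excluded'."""
    x = scheme.metric_value(quality)
    if scheme.metric == "fnat":
        if x > NATIVE_FNAT_CUTOFF:
            return "native"
    else:
        if x < NATIVE_IRMSD_CUTOFF:
            return "native"
    return "non_native" if _in_interval(x, scheme.interval) else "excluded"


@dataclass(slots=True)
class DecoyRecord:
    """One pose with its metrics and class under a given scheme."""

    decoy_id: str
    fnat: float
    irmsd: float
    label: str
    scheme: CategoryScheme
    source: Literal["reference", "docked", "synthetic"] = "synthetic"


@dataclass(slots=True)
class LabeledSet:
    """(feature vector, class) pairs ready for the classifier."""

    entries: list[tuple[FeatureVector, str]]
    flags: list[str] = field(default_factory=list)

    @property
    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for _, lab in self.entries:
            out[lab] = out.get(lab, 0) + 1
        return out

    def matrices(self) -> tuple[np.ndarray, np.ndarray]:
        X = np.array([fv.values for fv, _ in self.entries])
        y = np.array([1 if lab == "native" else 0 for _, lab in self.entries])
        return X, y

    def extend(self, other: "LabeledSet") -> None:
        self.entries.extend(other.entries)
        self.flags.extend(other.flags)


def assemble_examples(reference: DimerComplex,
                      decoys: Sequence[tuple[DimerComplex, DecoyQuality]],
                      scheme: CategoryScheme,
                      seed: int,
                      n_non_native: int = 10,
                      strict: bool = True,
                      feature_params: dict | None = None,
                      feature_cache: dict[str, FeatureVector] | None = None
                      ) -> LabeledSet:
    """Build the 1:5 per-reference training block (2 native, 10 non-native).

    Natives are the reference itself plus the single decoy with the best
    metric (highest FNAT / lowest iRMSD) among those passing the native
    cutoff; non-natives are sampled uniformly (seeded) from the decoys in
    the scheme's band. In strict mode a missing native-qualifying decoy or
    fewer than ``n_non_native`` in-band decoys is an error; lenient mode
    returns what exists and records a flag.

    ``feature_cache`` (pose label -> FeatureVector) lets callers assembling
    several band schemes from one decoy ladder extract each pose only once.
    """
    rng = np.random.default_rng(seed)
    feature_params = feature_params or {}

    def features_of(pose: DimerComplex) -> FeatureVector:
        if feature_cache is None:
            return extract_features(pose, **feature_params)
        if pose.label not in feature_cache:
            feature_cache[pose.label] = extract_features(pose,
                                                         **feature_params)
        return feature_cache[pose.label]

    scored = [(d, q, categorize(q, scheme)) for d, q in decoys]
    native_pool = [(d, q) for d, q, lab in scored if lab == "native"]
    band_pool = [(d, q) for d, q, lab in scored if lab == "non_native"]

    flags: list[str] = []
    entries: list[tuple[FeatureVector, str]] = []
    entries.append((features_of(reference), "native"))

    if native_pool:
        best = max(native_pool, key=lambda dq: scheme.metric_value(dq[1])) \
            if scheme.metric == "fnat" else \
            min(native_pool, key=lambda dq: scheme.metric_value(dq[1]))
        entries.append((features_of(best[0]), "native"))
    elif strict:
        raise ValueError("no decoy passes the native cutoff "
                         f"({scheme.metric} scheme)")
    else:
        flags.append("missing_second_native")

    if len(band_pool) < n_non_native:
        if strict:
            raise ValueError(
                f"only {len(band_pool)} decoys in the {scheme.band!r} band; "
                f"{n_non_native} required")
        flags.append("short_non_native_pool")
        chosen = list(range(len(band_pool)))
    else:
        chosen = rng.choice(len(band_pool), size=n_non_native,
                            replace=False).tolist()
    for i in sorted(chosen):
        entries.append((features_of(band_pool[i][0]), "non_native"))
    return LabeledSet(entries, flags)


def build_band_datasets(seed: int,
                        n_references: int = 8,
                        n_res_per_chain: int = 45,
                        metric: str = "fnat",
                        bands: Sequence[str] = ("high", "moderate", "weak"),
                        n_decoys: int = 60,
                        min_per_band: int = 10,
                        feature_params: dict | None = None
                        ) -> dict[str, LabeledSet]:
    """Synthetic references -> stratified ladders -> pooled 1:5 sets per band.

    For each of ``n_references`` seeded toy dimers a stratified decoy
    ladder is generated and a 2-native/10-non-native block assembled under
    each requested band of the chosen metric; blocks are pooled across
    references into one :class:`LabeledSet` per band. All sub-seeds derive
    from ``seed``.
    """
    out = {b: LabeledSet([]) for b in bands}
    for r in range(n_references):
        ref = make_toy_dimer(n_res_per_chain, seed=100_000 * seed + r)
        decoys = generate_decoys(ref, n_decoys,
                                 seed=200_000 * seed + r,
                                 stratified=True, min_per_band=min_per_band)
        cache: dict[str, FeatureVector] = {}
        for b in bands:
            block = assemble_examples(
                ref, decoys, CategoryScheme(metric, b),  # type: ignore[arg-type]
                seed=300_000 * seed + r,
                feature_params=feature_params, feature_cache=cache)
            out[b].extend(block)
    return out


# ---------------------------------------------------------------------------
# Synthetic dimers
# ---------------------------------------------------------------------------

#: Sampling weights for residue types, enriched for the types that dominate
#: real native interfaces (ARG, ASP, GLU, PHE, TYR, ILE).
_RESIDUE_WEIGHTS = {
    "ARG": 3.0, "ASP": 3.0, "GLU": 3.0, "PHE": 2.0, "TYR": 2.0, "ILE": 2.0,
    "ALA": 1.0, "ASN": 1.0, "CYS": 0.3, "GLN": 1.0, "GLY": 1.0, "HIS": 1.0,
    "LEU": 1.5, "LYS": 1.5, "MET": 0.5, "PRO": 0.5, "SER": 1.0, "THR": 1.0,
    "TRP": 0.5, "VAL": 1.5,
}

_CA_STEP = 3.8  # A, virtual CA-CA bond


def _compact_ca_walk(n: int, rng: np.random.Generator) -> np.ndarray:
    """Self-avoiding random walk with a centroid-attraction compactness bias."""
    for _ in range(50):  # whole-walk retries on self-collision dead ends
        pts = [np.zeros(3)]
        direction = _unit(rng.normal(size=3))
        ok = True
        for _ in range(n - 1):
            placed = False
            for _ in range(60):
                centroid = np.mean(pts, axis=0)
                pull = centroid - pts[-1]
                pull = pull / (np.linalg.norm(pull) + 1e-9)
                proposal = _unit(0.9 * direction + 0.55 * rng.normal(size=3)
                                 + 0.25 * pull)
                cand = pts[-1] + _CA_STEP * proposal
                d = np.linalg.norm(np.array(pts[:-1]) - cand, axis=1) \
                    if len(pts) > 1 else np.array([np.inf])
                if (d > 3.6).all():
                    pts.append(cand)
                    direction = proposal
                    placed = True
                    break
            if not placed:
                ok = False
                break
        if ok:
            return np.array(pts)
    raise RuntimeError("could not build a self-avoiding CA walk")


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _backbone_from_ca(ca: np.ndarray) -> list[dict[str, np.ndarray]]:
    """Place N, C, O, CB around each CA using local frames of the CA trace.

    Idealised geometry only: offsets are fixed-length vectors in the frame
    spanned by the chain direction and its normal, adequate for SASA,
    contact and RMSD arithmetic (not for chemistry).
    """
    n = len(ca)
    out: list[dict[str, np.ndarray]] = []
    for i in range(n):
        prev_v = ca[i] - ca[i - 1] if i > 0 else ca[i] - (ca[i + 1]
                                                          - ca[i]) - ca[i]
        next_v = ca[i + 1] - ca[i] if i < n - 1 else ca[i] - ca[i - 1]
        t = _unit(next_v + (prev_v if i > 0 else next_v))
        ref = np.array([0.0, 0.0, 1.0])
        if abs(np.dot(t, ref)) > 0.9:
            ref = np.array([1.0, 0.0, 0.0])
        u = _unit(np.cross(t, ref))
        w = np.cross(t, u)
        atoms = {
            "CA": ca[i],
            "N": ca[i] - 1.46 * t + 0.35 * u,
            "C": ca[i] + 1.52 * t + 0.30 * u,
            "O": ca[i] + 1.52 * t + 0.30 * u + 1.23 * w,
            "CB": ca[i] - 1.53 * u + 0.35 * w,
        }
        out.append(atoms)
    return out


_ELEMENT = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C"}


def _build_chain(n_res: int, chain_id: str, rng: np.random.Generator,
                 serial_start: int = 1) -> list[AtomRecord]:
    ca = _compact_ca_walk(n_res, rng)
    backbone = _backbone_from_ca(ca)
    names = list(_RESIDUE_WEIGHTS)
    weights = np.array([_RESIDUE_WEIGHTS[r] for r in names])
    weights = weights / weights.sum()
    types = rng.choice(names, size=n_res, p=weights)
    atoms: list[AtomRecord] = []
    serial = serial_start
    for i, (res, placed) in enumerate(zip(types, backbone), start=1):
        for atom_name in ("N", "CA", "C", "O", "CB"):
            if res == "GLY" and atom_name == "CB":
                continue
            x, y, z = placed[atom_name]
            atoms.append(AtomRecord(serial, atom_name, _ELEMENT[atom_name],
                                    "", str(res), chain_id, i, "",
                                    float(x), float(y), float(z)))
            serial += 1
    return atoms


def _min_cross_distance(a: np.ndarray, b: np.ndarray) -> float:
    ta = cKDTree(a)
    d, _ = ta.query(b, k=1)
    return float(np.min(d))


def _dock_ligand(receptor: list[AtomRecord], ligand: list[AtomRecord],
                 rng: np.random.Generator,
                 contact_distance: float = 3.3,
                 n_orientations: int = 16) -> list[AtomRecord]:
    """Dock the ligand against the receptor, maximising interface contacts.

    Each of ``n_orientations`` seeded candidates randomly re-orients the
    ligand and slides it along a random approach direction (bisection on
    the approach distance) until the minimal cross-chain heavy-atom
    distance equals ``contact_distance``; the candidate producing the most
    residue-residue contacts at 5 A wins. Rough-surfaced random-walk chains
    meet nearly tangentially in most orientations, so taking the best of
    several is what produces a realistically broad contact patch.
    """
    rxyz = coords_of(receptor)
    rcen = rxyz.mean(axis=0)
    tree = cKDTree(rxyz)
    best: list[AtomRecord] | None = None
    best_contacts = -1
    for _ in range(n_orientations):
        rot = Rotation.random(rng=rng).as_matrix()
        lig = rigid_transform(ligand, rot, np.zeros(3))
        lxyz = coords_of(lig)
        lcen = lxyz.mean(axis=0)
        u = _unit(rng.normal(size=3))
        lo, hi = 0.0, 120.0
        for _ in range(40):
            mid = 0.5 * (lo + hi)
            d, _idx = tree.query(lxyz - lcen + rcen + mid * u, k=1)
            if float(np.min(d)) < contact_distance:
                lo = mid
            else:
                hi = mid
        docked = rigid_transform(lig, np.eye(3), rcen + hi * u - lcen)
        n_contacts = len(residue_contacts(DimerComplex(receptor, docked)))
        if n_contacts > best_contacts:
            best_contacts, best = n_contacts, docked
    assert best is not None
    return best


def make_toy_dimer(n_res_per_chain: int, seed: int,
                   min_interface_fraction: float = 0.2,
                   min_contacts: int = 8,
                   max_retries: int = 40) -> DimerComplex:
    """Generate a compact two-chain synthetic complex with a real interface.

    Both chains are seeded compact CA walks dressed with idealised backbone
    atoms; the second chain is docked against the first so that at least
    ``min_interface_fraction`` of all residues are interfacial (10 A
    heavy-atom criterion) and the interface carries at least
    ``min_contacts`` residue-residue contacts at 5 A (enough granularity
    for the FNAT bands). Deterministic for a given (n, seed).
    """
    if n_res_per_chain < 5:
        raise ValueError("need at least 5 residues per chain")
    rng = np.random.default_rng(seed)
    for attempt in range(max_retries):
        receptor = _build_chain(n_res_per_chain, "A", rng)
        ligand0 = _build_chain(n_res_per_chain, "B", rng,
                               serial_start=receptor[-1].serial + 1)
        ligand = _dock_ligand(receptor, ligand0, rng)
        dimer = DimerComplex(receptor, ligand,
                             label=f"toy_n{n_res_per_chain}_s{seed}")
        rset, lset = interface_residues(
            dimer, InterfaceDefinition("contact_distance", 10.0))
        frac = (len(rset) + len(lset)) / (2 * n_res_per_chain)
        if frac >= min_interface_fraction and \
                len(residue_contacts(dimer)) >= min_contacts:
            return dimer
    raise RuntimeError(f"failed to reach a {min_interface_fraction:.0%} "
                       f"interface in {max_retries} placements")


# ---------------------------------------------------------------------------
# Decoy generation
# ---------------------------------------------------------------------------

def _perturb_ligand(reference: DimerComplex, rng: np.random.Generator,
                    angle_range: tuple[float, float],
                    shift_range: tuple[float, float],
                    outward_bias: float = 0.0) -> DimerComplex:
    """One rigid-body pose: rotate the ligand about its own centroid by a
    random angle in ``angle_range`` (deg) and translate it by a random
    magnitude in ``shift_range`` (A).

    ``outward_bias`` > 0 tilts the translation direction away from the
    receptor (mixing the outward unit vector with isotropic noise), which
    is how completely dissociated, maximally non-native poses arise.
    """
    lig = reference.ligand
    lxyz = coords_of(lig)
    centre = lxyz.mean(axis=0)
    angle = math.radians(rng.uniform(*angle_range))
    axis = _unit(rng.normal(size=3))
    R = Rotation.from_rotvec(angle * axis).as_matrix()
    direction = rng.normal(size=3)
    if outward_bias > 0.0:
        outward = _unit(centre - coords_of(reference.receptor).mean(axis=0))
        direction = outward_bias * outward + (1 - outward_bias) \
            * _unit(direction)
    shift = rng.uniform(*shift_range) * _unit(direction)
    t = centre - R @ centre + shift
    return DimerComplex(list(reference.receptor),
                        rigid_transform(lig, R, t), reference.label)


def _is_clash_free(dimer: DimerComplex, max_clash_overlap: float) -> bool:
    return _min_cross_distance(coords_of(dimer.receptor),
                               coords_of(dimer.ligand)) >= max_clash_overlap


# proposal schedule (angle range deg, shift range A, outward bias), spanning
# gentle perturbations (native-like) through complete dissociation; all
# rungs stay within the 0-180 deg / 0-25 A sampling envelope
_PROPOSAL_LADDER = (
    ((0.0, 4.0), (0.0, 0.6), 0.0),
    ((0.0, 10.0), (0.0, 1.5), 0.0),
    ((0.0, 25.0), (0.0, 3.5), 0.0),
    ((0.0, 60.0), (0.0, 8.0), 0.0),
    ((0.0, 180.0), (0.0, 25.0), 0.0),
    ((120.0, 180.0), (15.0, 25.0), 0.8),
)


def generate_decoys(reference: DimerComplex, n: int, seed: int,
                    max_clash_overlap: float = 2.0,
                    stratified: bool = False,
                    min_per_band: int = 3,
                    max_attempts_factor: int = 400,
                    ) -> list[tuple[DimerComplex, DecoyQuality]]:
    """Emulate rigid-body docking output for one reference complex.

    Poses are seeded random rotations (0-180 deg) / translations (0-25 A)
    of the ligand; any pose with a cross-chain heavy-atom distance below
    ``max_clash_overlap`` is rejected. Each returned pose carries its FNAT
    and iRMSD versus the reference.

    In stratified mode sampling cycles through a gentle-to-violent proposal
    schedule and continues past ``n`` until every FNAT band, every iRMSD
    band and the native region hold at least ``min_per_band`` poses; if the
    attempt budget runs out first, the empty bands are named in the error.
    """
    scorer = DecoyScorer(reference)
    rng = np.random.default_rng(seed)
    out: list[tuple[DimerComplex, DecoyQuality]] = []

    def band_counts() -> dict[str, int]:
        counts = {f"fnat:{b}": 0 for b in ("high", "moderate", "weak")}
        counts.update({f"irmsd:{b}": 0 for b in ("high", "moderate", "weak")})
        counts["native"] = 0
        for _, q in out:
            if q.fnat > NATIVE_FNAT_CUTOFF or q.irmsd < NATIVE_IRMSD_CUTOFF:
                counts["native"] += 1
            for b in ("high", "moderate", "weak"):
                if q.fnat <= NATIVE_FNAT_CUTOFF and \
                        _in_interval(q.fnat, FNAT_BANDS[b]):
                    counts[f"fnat:{b}"] += 1
                if q.irmsd >= NATIVE_IRMSD_CUTOFF and \
                        _in_interval(q.irmsd, IRMSD_BANDS[b]):
                    counts[f"irmsd:{b}"] += 1
        return counts

    def satisfied() -> bool:
        if len(out) < n:
            return False
        if not stratified:
            return True
        return all(v >= min_per_band for v in band_counts().values())

    max_attempts = max_attempts_factor * max(n, 1)
    attempt = 0
    ladder_i = 0
    while not satisfied():
        if attempt >= max_attempts:
            if stratified:
                empty = [k for k, v in band_counts().items()
                         if v < min_per_band]
                raise RuntimeError(
                    "stratification unreachable within the attempt budget; "
                    f"underfilled bands: {empty}")
            break
        attempt += 1
        if stratified:
            angle_range, shift_range, outward = _PROPOSAL_LADDER[ladder_i]
            ladder_i = (ladder_i + 1) % len(_PROPOSAL_LADDER)
        else:
            angle_range, shift_range, outward = (0.0, 180.0), (0.0, 25.0), 0.0
        pose = _perturb_ligand(reference, rng, angle_range, shift_range,
                               outward)
        if not _is_clash_free(pose, max_clash_overlap):
            continue
        pose = DimerComplex(pose.receptor, pose.ligand,
                            label=f"{reference.label}_d{len(out):04d}")
        out.append((pose, scorer.score(pose)))
    return out
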