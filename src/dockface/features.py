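"""Fixed-schema interface descriptors and native/non-native screening.

One interface is summarised by a 274-entry vector: per-residue-type
accessible surface area of the interface residues (20), per-type buried
surface area (20), interface residue-type frequencies (20), hydrogen-bond
counts per unordered residue-type pair (210 = 20 + C(20,2)), total H-bond
count, salt-bridge count, total interface area (= sum BSA / 2), and the
desolvation dG surrogate. Interface membership uses the area-based
definition (BSA > 0.1 A^2).

Vectors are positionally comparable: the schema fixes name order and
carries a version tag so persisted matrices and models can refuse
mismatched layouts.

Group screening uses a two-sided Mann-Whitney U test per feature, flagging
features with p <= alpha (0.01 by default); constant features get p = 1.
No multiple-testing correction is applied by default, but Benjamini-
Hochberg is available.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations_with_replacement
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .structure import STANDARD_RESIDUES, DimerComplex
from .interface import (BSA_INTERFACE_THRESHOLD, InterfaceDefinition,
                        hydrogen_bonds, salt_bridges)
from . import sasa as _sasa

__all__ = [
    "FeatureSchema",
    "FeatureVector",
    "default_schema",
    "extract_features",
    "feature_significance",
    "write_feature_table",
    "read_feature_table",
]

SCHEMA_VERSION = "1.0"

_RESIDUE_PAIRS: tuple[tuple[str, str], ...] = tuple(
    combinations_with_replacement(sorted(STANDARD_RESIDUES), 2))


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered, versioned feature-name list; vectors align to it by position."""

    names: tuple[str, ...]
    version: str = SCHEMA_VERSION

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")

    def __len__(self) -> int:
        return len(self.names)

    def to_json(self) -> str:
        return json.dumps({"version": self.version, "names": list(self.names)})

    @classmethod
    def from_json(cls, text: str) -> "FeatureSchema":
        obj = json.loads(text)
        return cls(tuple(obj["names"]), obj["version"])


def default_schema() -> FeatureSchema:
    names: list[str] = []
    names += [f"asa_{r}" for r in sorted(STANDARD_RESIDUES)]
    names += [f"bsa_{r}" for r in sorted(STANDARD_RESIDUES)]
    names += [f"comp_{r}" for r in sorted(STANDARD_RESIDUES)]
    names += [f"hb_{a}_{b}" for a, b in _RESIDUE_PAIRS]
    names += ["hb_total", "salt_bridges", "interface_area", "delta_g"]
    return FeatureSchema(tuple(names))


_DEFAULT_SCHEMA = default_schema()


@dataclass(frozen=True)
class FeatureVector:
    """Values aligned to a schema, plus provenance and the no-interface flag."""

    values: np.ndarray
    schema: FeatureSchema = field(default_factory=default_schema)
    label: str = ""
    no_interface: bool = False

    def __post_init__(self) -> None:
        if len(self.values) != len(self.schema):
            raise ValueError("vector length does not match schema")

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.schema.names.index(name)])


def extract_features(dimer: DimerComplex,
                     bsa_threshold: float = BSA_INTERFACE_THRESHOLD,
                     hbond_dmax: float | None = None,
                     salt_dmax: float | None = None,
                     sasa_params: dict | None = None,
                     schema: FeatureSchema | None = None) -> FeatureVector:
    """Compute the full interface descriptor vector for one dimer pose.

    A pose with no buried residues (separated or non-binding chains) gets
    an all-zero vector with ``no_interface=True`` so it can still be scored.
    """
    schema = schema or _DEFAULT_SCHEMA
    sasa_params = sasa_params or {}
    datom, bound, _, _ = _sasa.atom_delta_asa(dimer, **sasa_params)

    bsa_by_res: dict = {}
    for a, d in zip(dimer.atoms, datom):
        key = a.residue_key
        bsa_by_res[key] = bsa_by_res.get(key, 0.0) + float(d)
    iface = {k for k, v in bsa_by_res.items() if v > bsa_threshold}

    values = np.zeros(len(schema))
    if not iface:
        return FeatureVector(values, schema, dimer.label, no_interface=True)

    idx = {name: i for i, name in enumerate(schema.names)}
    asa_by_res = bound.residue_area
    for key in iface:
        r = key.residue_name
        values[idx[f"asa_{r}"]] += asa_by_res.get(key, 0.0)
        values[idx[f"bsa_{r}"]] += bsa_by_res[key]
        values[idx[f"comp_{r}"]] += 1.0
    comp_cols = [idx[f"comp_{r}"] for r in sorted(STANDARD_RESIDUES)]
    values[comp_cols] /= len(iface)

    hb_kwargs = {} if hbond_dmax is None else {"d_max": hbond_dmax}
    bonds = hydrogen_bonds(dimer, **hb_kwargs)
    for b in bonds:
        values[idx[f"hb_{b.residue_pair[0]}_{b.residue_pair[1]}"]] += 1.0
    values[idx["hb_total"]] = len(bonds)

    sb_kwargs = {} if salt_dmax is None else {"d_max": salt_dmax}
    values[idx["salt_bridges"]] = len(salt_bridges(dimer, **sb_kwargs))

    total_bsa = sum(bsa_by_res[k] for k in iface)
    values[idx["interface_area"]] = total_bsa / 2.0
    values[idx["delta_g"]] = _sasa.solvation_delta_g(
        dimer, precomputed_delta=datom)
    return FeatureVector(values, schema, dimer.label)


# ---------------------------------------------------------------------------
# Group screening
# ---------------------------------------------------------------------------

def _as_matrix(group: Sequence[FeatureVector] | np.ndarray) -> np.ndarray:
    if isinstance(group, np.ndarray):
        return np.asarray(group, dtype=float)
    return np.array([fv.values for fv in group], dtype=float)


def feature_significance(native: Sequence[FeatureVector] | np.ndarray,
                         non_native: Sequence[FeatureVector] | np.ndarray,
                         alpha: float = 0.01,
                         schema: FeatureSchema | None = None,
                         bh_correct: bool = False) -> pd.DataFrame:
    """Per-feature two-sided Mann-Whitney U comparison of the two groups.

    Returns a DataFrame indexed by feature name with columns ``p_value``
    and ``significant`` (p <= alpha). Features constant across the pooled
    data are reported with p = 1. ``bh_correct=True`` applies Benjamini-
    Hochberg before thresholding (off by default).
    """
    X, Y = _as_matrix(native), _as_matrix(non_native)
    if X.shape[0] < 3 or Y.shape[0] < 3:
        raise ValueError("need at least 3 samples per group")
    schema = schema or _DEFAULT_SCHEMA
    if X.shape[1] != len(schema) or Y.shape[1] != len(schema):
        raise ValueError("feature matrices do not match the schema")

    p = np.ones(X.shape[1])
    pooled = np.vstack([X, Y])
    varying = ~np.all(pooled == pooled[0], axis=0)
    if varying.any():
        res = stats.mannwhitneyu(X[:, varying], Y[:, varying],
                                 alternative="two-sided", axis=0)
        p[varying] = res.pvalue
    if bh_correct:
        p_thresh = stats.false_discovery_control(p, method="bh")
        significant = p_thresh <= alpha
    else:
        significant = p <= alpha
    return pd.DataFrame({"p_value": p, "significant": significant},
                        index=list(schema.names))


# ---------------------------------------------------------------------------
# Tabular IO
# ---------------------------------------------------------------------------

def write_feature_table(path: str | Path,
                        vectors: Sequence[FeatureVector],
                        labels: Sequence[str] | None = None) -> None:
    """Write vectors as a TSV (header = schema names) plus a schema JSON."""
    path = Path(path)
    schema = vectors[0].schema
    df = pd.DataFrame(_as_matrix(vectors), columns=list(schema.names))
    df.insert(0, "sample", [fv.label for fv in vectors])
    if labels is not None:
        df.insert(1, "class", list(labels))
    df.to_csv(path, sep="\t", index=False)
    path.with_suffix(path.suffix + ".schema.json").write_text(
        schema.to_json())


def read_feature_table(path: str | Path
                       ) -> tuple[np.ndarray, list[str], list[str] | None,
                                  FeatureSchema]:
    """Read a feature TSV; returns (matrix, sample ids, class labels, schema)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    schema_path = path.with_suffix(path.suffix + ".schema.json")
    meta_cols = [c for c in ("sample", "class") if c in df.columns]
    feature_cols = [c for c in df.columns if c not in meta_cols]
    if schema_path.exists():
        schema = FeatureSchema.from_json(schema_path.read_text())
        if list(schema.names) != feature_cols:
            raise ValueError("feature table columns do not match its schema")
    else:
        schema = FeatureSchema(tuple(feature_cols))
    labels = df["class"].astype(str).tolist() if "class" in df else None
    samples = df["sample"].astype(str).tolist() if "sample" in df \
        else [str(i) for i in range(len(df))]
    return df[feature_cols].to_numpy(dtype=float), samples, labels, schema
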