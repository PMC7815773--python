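"""Shared fixtures: hand-written PDB text and seeded synthetic complexes."""

from __future__ import annotations

import numpy as np
import pytest

from dockface import make_toy_dimer, generate_decoys


def atom_line(serial: int, name: str, res: str, chain: str, seq: int,
              x: float, y: float, z: float, element: str = "",
              alt_loc: str = " ", icode: str = " ",
              record: str = "ATOM  ", occ: float = 1.0) -> str:
    """One fixed-column PDB ATOM/HETATM line, built independently of the
    package's writer."""
    element = element or name[0]
    padded = name if len(name) >= 4 else f" {name:<3}"
    return (f"{record}{serial:>5} {padded}{alt_loc}{res:>3} {chain}"
            f"{seq:>4}{icode}   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}"
            f"{0.0:6.2f}          {element:>2}")


def make_pdb(lines: list[str]) -> str:
    return "\n".join(lines + ["END"]) + "\n"


@pytest.fixture(scope="session")
def toy30():
    """Deterministic 30-residue-per-chain synthetic reference complex."""
    return make_toy_dimer(30, seed=1)


@pytest.fixture(scope="session")
def toy45():
    """Larger synthetic complex able to reach the far iRMSD band."""
    return make_toy_dimer(45, seed=1)


@pytest.fixture(scope="session")
def ladder30(toy30):
    """Small stratified decoy ladder shared across metric/dataset tests."""
    return generate_decoys(toy30, 20, seed=7, stratified=True,
                           min_per_band=3)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
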