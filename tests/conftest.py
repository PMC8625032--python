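import numpy as np
import pytest

from templig.chem_io import (AtomRecord, Chain, ProteinStructure, Residue)
from templig.fixtures import make_fixture_molecule, make_toy_library, make_toy_pocket

AMINO_ACIDS = ["ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS",
               "ILE", "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP",
               "TYR", "VAL"]


@pytest.fixture(scope="session")
def aspirin():
    return make_fixture_molecule(1)


@pytest.fixture(scope="session")
def pocket(aspirin):
    return make_toy_pocket(aspirin)


@pytest.fixture(scope="session")
def identical_library():
    return make_toy_library(3, "identical", seed=3)


def random_ca_chain(seed: int, length: int = 40) -> ProteinStructure:
    """Random-sequence, random-coordinate CA-only chain (no homology)."""
    rng = np.random.default_rng(seed)
    residues = [Residue(AMINO_ACIDS[int(rng.integers(20))], i + 1,
                        [AtomRecord("CA", "C", rng.normal(size=3) * 10)])
                for i in range(length)]
    return ProteinStructure([Chain("A", residues)])


def helix_protein(sequence: str, chain_id: str = "A") -> ProteinStructure:
    """Idealized CA-trace helix for a given one-letter sequence."""
    one_to_three = {v: k for k, v in {
        "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
        "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
        "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
        "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V"}.items()}
    residues = []
    for i, aa in enumerate(sequence):
        theta = 100.0 * np.pi / 180.0 * i
        coord = np.array([2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * i])
        residues.append(Residue(one_to_three[aa], i + 1,
                                [AtomRecord("CA", "C", coord)]))
    return ProteinStructure([Chain(chain_id, residues)])
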