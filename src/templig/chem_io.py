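"""Molecular structure containers and I/O.

Small molecules are held in a light :class:`Molecule` container (elements,
coordinates, bonds) with lazy conversion to RDKit for graph-level work;
proteins are parsed from PDB text with gemmi into :class:`ProteinStructure`.
Protein-frame matching follows the classic recipe: global sequence alignment
of the chains followed by least-squares (Kabsch) superposition of the aligned
alpha-carbons.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import gemmi
import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from rdkit import Chem, Geometry
from rdkit.Chem import Descriptors

from . import config


class ChemIOError(ValueError):
    """Base class for structure-reading failures."""


class NoLigandError(ChemIOError):
    pass


class AmbiguousLigandError(ChemIOError):
    pass


class UnalignableError(ChemIOError):
    pass


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass
class Molecule:
    """Heavy-atom chemistry + 3D coordinates of a small molecule."""

    elements: list[str]
    coords: np.ndarray                      # (n, 3) Angstrom
    bonds: list[tuple[int, int, float]]     # (i, j, order)
    charges: list[int] = field(default_factory=list)
    name: str = ""
    smiles: Optional[str] = None
    _rdkit: Optional[Chem.Mol] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if len(self.elements) < 1:
            raise ValueError("molecule needs at least one heavy atom")
        if len(self.elements) != len(self.coords):
            raise ValueError("elements/coords length mismatch")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        n = len(self.elements)
        for i, j, _ in self.bonds:
            if not (0 <= i < n and 0 <= j < n and i != j):
                raise ValueError(f"invalid bond ({i},{j}) for {n} atoms")
        if not self.charges:
            self.charges = [0] * n

    @property
    def num_atoms(self) -> int:
        return len(self.elements)

    @property
    def centroid(self) -> np.ndarray:
        return self.coords.mean(axis=0)

    @property
    def molecular_weight(self) -> float:
        """Molecular weight in Da, implicit hydrogens included."""
        return float(Descriptors.MolWt(self.to_rdkit()))

    def to_rdkit(self) -> Chem.Mol:
        """RDKit molecule with a single conformer carrying ``coords``."""
        if self._rdkit is not None:
            mol = Chem.Mol(self._rdkit)
        else:
            rw = Chem.RWMol()
            for el, q in zip(self.elements, self.charges):
                a = Chem.Atom(el)
                a.SetFormalCharge(int(q))
                a.SetNoImplicit(False)
                rw.AddAtom(a)
            order_map = {1.0: Chem.BondType.SINGLE, 2.0: Chem.BondType.DOUBLE,
                         3.0: Chem.BondType.TRIPLE, 1.5: Chem.BondType.AROMATIC}
            for i, j, o in self.bonds:
                rw.AddBond(int(i), int(j), order_map.get(float(o), Chem.BondType.SINGLE))
            mol = rw.GetMol()
            try:
                Chem.SanitizeMol(mol)
            except Exception:
                # PDB-derived ligands lack bond orders; fall back to a
                # connectivity-only sanitization.
                mol = rw.GetMol()
                Chem.SanitizeMol(
                    mol,
                    Chem.SanitizeFlags.SANITIZE_ALL
                    ^ Chem.SanitizeFlags.SANITIZE_KEKULIZE
                    ^ Chem.SanitizeFlags.SANITIZE_SETAROMATICITY
                    ^ Chem.SanitizeFlags.SANITIZE_PROPERTIES,
                )
            self._rdkit = Chem.Mol(mol)
            mol = Chem.Mol(self._rdkit)
        conf = Chem.Conformer(self.num_atoms)
        for i, xyz in enumerate(self.coords):
            conf.SetAtomPosition(i, Geometry.Point3D(*(float(v) for v in xyz)))
        mol.RemoveAllConformers()
        mol.AddConformer(conf, assignId=True)
        return mol

    def with_coords(self, coords: np.ndarray) -> "Molecule":
        """Copy of this molecule with new coordinates (same graph)."""
        return replace(self, coords=np.asarray(coords, dtype=float).copy())

    @classmethod
    def from_rdkit(cls, mol: Chem.Mol, conf_id: int = -1,
                   name: str = "", smiles: Optional[str] = None) -> "Molecule":
        heavy = Chem.RemoveHs(Chem.Mol(mol))
        conf = heavy.GetConformer(conf_id)
        coords = np.array([[conf.GetAtomPosition(i).x,
                            conf.GetAtomPosition(i).y,
                            conf.GetAtomPosition(i).z]
                           for i in range(heavy.GetNumAtoms())])
        bonds = [(b.GetBeginAtomIdx(), b.GetEndAtomIdx(), b.GetBondTypeAsDouble())
                 for b in heavy.GetBonds()]
        out = cls(elements=[a.GetSymbol() for a in heavy.GetAtoms()],
                  coords=coords, bonds=bonds,
                  charges=[a.GetFormalCharge() for a in heavy.GetAtoms()],
                  name=name or (mol.GetProp("_Name") if mol.HasProp("_Name") else ""),
                  smiles=smiles)
        out._rdkit = heavy
        return out


@dataclass
class AtomRecord:
    name: str
    element: str
    coord: np.ndarray


@dataclass
class Residue:
    name: str
    seq_index: int
    atoms: list[AtomRecord]

    def get_atom(self, name: str) -> Optional[AtomRecord]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue]

    @property
    def sequence(self) -> str:
        return "".join(_THREE_TO_ONE.get(r.name, "X") for r in self.residues)

    def ca_coords(self) -> np.ndarray:
        out = []
        for r in self.residues:
            ca = r.get_atom("CA")
            if ca is not None:
                out.append(ca.coord)
        return np.array(out) if out else np.zeros((0, 3))


@dataclass
class ProteinStructure:
    chains: list[Chain]
    name: str = ""

    def __post_init__(self) -> None:
        for ch in self.chains:
            idx = [r.seq_index for r in ch.residues]
            if any(b <= a for a, b in zip(idx, idx[1:])):
                raise ValueError(f"residue indices not strictly increasing in chain {ch.chain_id}")

    @property
    def num_atoms(self) -> int:
        return sum(len(r.atoms) for ch in self.chains for r in ch.residues)

    def all_coords(self) -> np.ndarray:
        pts = [a.coord for ch in self.chains for r in ch.residues for a in r.atoms]
        return np.array(pts) if pts else np.zeros((0, 3))

    def all_elements(self) -> list[str]:
        return [a.element for ch in self.chains for r in ch.residues for a in r.atoms]

    def transformed(self, transform: "RigidTransform") -> "ProteinStructure":
        chains = []
        for ch in self.chains:
            residues = []
            for r in ch.residues:
                atoms = [AtomRecord(a.name, a.element, transform.apply(a.coord[None])[0])
                         for a in r.atoms]
                residues.append(Residue(r.name, r.seq_index, atoms))
            chains.append(Chain(ch.chain_id, residues))
        return ProteinStructure(chains, name=self.name)


@dataclass
class ComplexEntry:
    """One protein + one co-bound ligand, with curation metadata."""

    protein: ProteinStructure
    ligand: Molecule
    pdb_id: str = ""
    r_free: Optional[float] = None
    uniprot_id: Optional[str] = None
    binding_site_center: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.binding_site_center is None:
            self.binding_site_center = self.ligand.centroid
        self.binding_site_center = np.asarray(self.binding_site_center, dtype=float)


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x -> R x + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-6) or np.linalg.det(R) < 0:
            raise ValueError("rotation must be orthonormal with det +1")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equivalent to applying ``other`` first, then ``self``."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)


_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V", "MSE": "M",
}

_AMINO_ACIDS = set(_THREE_TO_ONE)


# --------------------------------------------------------------------------
# PDB complex reading
# --------------------------------------------------------------------------

def _perceive_bonds(elements: Sequence[str], coords: np.ndarray,
                    tolerance: float = config.BOND_TOLERANCE) -> list[tuple[int, int, float]]:
    """Single bonds wherever two atoms sit within covalent-radius sum + tol."""
    n = len(elements)
    radii = np.array([config.COVALENT_RADII.get(el, 0.77) for el in elements])
    bonds = []
    d = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
    for i in range(n):
        for j in range(i + 1, n):
            if d[i, j] <= radii[i] + radii[j] + tolerance:
                bonds.append((i, j, 1.0))
    return bonds


def read_protein(pdb_text: str) -> ProteinStructure:
    """Protein chains only (every residue kept, ligands and waters ignored)."""
    st = gemmi.read_pdb_string(pdb_text)
    model = st[0]
    chains = []
    for ch in model:
        residues = []
        seen: set[int] = set()
        for res in ch:
            if res.name in config.LIGAND_EXCLUDE or res.seqid.num in seen:
                continue
            atoms = [AtomRecord(a.name, a.element.name,
                                np.array([a.pos.x, a.pos.y, a.pos.z]))
                     for a in res]
            residues.append(Residue(res.name, res.seqid.num, atoms))
            seen.add(res.seqid.num)
        if residues:
            chains.append(Chain(ch.name, residues))
    return ProteinStructure(chains, name=st.name or "")


def read_complex(pdb_text: str, ligand_selector: str = "auto") -> ComplexEntry:
    """Split a PDB file into protein chains and one co-bound ligand.

    ``ligand_selector`` is either a HETATM residue name or ``"auto"``, which
    requires exactly one candidate ligand after applying the exclusion list
    (waters, monoatomic ions, common buffer/cryo additives).
    """
    st = gemmi.read_pdb_string(pdb_text)
    st.setup_entities()
    model = st[0]

    chains: list[Chain] = []
    het_groups: dict[tuple[str, int, str], list[AtomRecord]] = {}
    het_names: dict[tuple[str, int, str], str] = {}

    for ch in model:
        residues = []
        for res in ch:
            atoms = [AtomRecord(a.name, a.element.name,
                                np.array([a.pos.x, a.pos.y, a.pos.z]))
                     for a in res]
            if res.name in _AMINO_ACIDS and res.get_ca() is not None:
                residues.append(Residue(res.name, res.seqid.num, atoms))
            elif res.het_flag == "H" or res.name not in _AMINO_ACIDS:
                key = (ch.name, res.seqid.num, res.name)
                het_groups[key] = atoms
                het_names[key] = res.name
        if residues:
            # drop duplicated seq ids (altloc leftovers) keeping the first
            seen: set[int] = set()
            uniq = []
            for r in residues:
                if r.seq_index not in seen:
                    uniq.append(r)
                    seen.add(r.seq_index)
            chains.append(Chain(ch.name, uniq))

    protein = ProteinStructure(chains, name=st.name or "")

    def excluded(key: tuple[str, int, str]) -> bool:
        name = het_names[key]
        if name in config.LIGAND_EXCLUDE:
            return True
        heavy = [a for a in het_groups[key] if a.element != "H"]
        return len(heavy) <= 1      # monoatomic ions regardless of name

    candidates = {k: v for k, v in het_groups.items() if not excluded(k)}
    if ligand_selector != "auto":
        candidates = {k: v for k, v in candidates.items() if k[2] == ligand_selector}
    if not candidates:
        raise NoLigandError("no-ligand: no candidate HETATM group found")
    if ligand_selector == "auto" and len(candidates) > 1:
        names = sorted({k[2] for k in candidates})
        raise AmbiguousLigandError(f"ambiguous-ligand: candidates {names}")
    key = sorted(candidates)[0]
    atoms = [a for a in candidates[key] if a.element != "H"]
    coords = np.array([a.coord for a in atoms])
    elements = [a.element for a in atoms]
    ligand = Molecule(elements=elements, coords=coords,
                      bonds=_perceive_bonds(elements, coords),
                      name=key[2])
    return ComplexEntry(protein=protein, ligand=ligand,
                        pdb_id=st.name or "", binding_site_center=ligand.centroid)


# --------------------------------------------------------------------------
# protein matching
# --------------------------------------------------------------------------

def _kabsch(P: np.ndarray, Q: np.ndarray) -> RigidTransform:
    """Least-squares rigid transform mapping Q onto P."""
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (Q - qc).T @ (P - pc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return RigidTransform(R, pc - R @ qc)


def match_proteins(reference: ProteinStructure, mobile: ProteinStructure,
                   min_aligned: int = 8,
                   min_identity: float = config.MATCH_MIN_IDENTITY,
                   prune: bool = False) -> RigidTransform:
    """Transform bringing ``mobile`` into the frame of ``reference``.

    Chains are paired greedily by best global alignment score (BLOSUM62);
    aligned alpha-carbon pairs feed a Kabsch superposition. With ``prune``
    the worst-fitting pairs (> 2x mean deviation) are iteratively dropped,
    mirroring the behaviour of interactive structure-matching tools.
    """
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aligner.mode = "global"

    pairs_P: list[np.ndarray] = []
    pairs_Q: list[np.ndarray] = []
    n_ident = 0
    n_aligned = 0
    used_mobile: set[int] = set()
    for ref_chain in reference.chains:
        best = None
        for mi, mob_chain in enumerate(mobile.chains):
            if mi in used_mobile:
                continue
            try:
                aln = aligner.align(ref_chain.sequence, mob_chain.sequence)[0]
            except Exception:
                continue
            if best is None or aln.score > best[0]:
                best = (aln.score, mi, aln)
        if best is None:
            continue
        _, mi, aln = best
        used_mobile.add(mi)
        mob_chain = mobile.chains[mi]
        for (rs, re_), (ms, me) in zip(*aln.aligned):
            for k in range(re_ - rs):
                r_res = ref_chain.residues[rs + k]
                m_res = mob_chain.residues[ms + k]
                r_ca, m_ca = r_res.get_atom("CA"), m_res.get_atom("CA")
                if r_ca is None or m_ca is None:
                    continue
                n_aligned += 1
                if r_res.name == m_res.name:
                    n_ident += 1
                pairs_P.append(r_ca.coord)
                pairs_Q.append(m_ca.coord)

    if n_aligned < min_aligned or n_ident < min_identity * max(n_aligned, 1):
        raise UnalignableError(
            f"unalignable: {n_aligned} aligned CA pairs, "
            f"identity {n_ident / max(n_aligned, 1):.2f}")

    P, Q = np.array(pairs_P), np.array(pairs_Q)
    tf = _kabsch(P, Q)
    if prune:
        for _ in range(5):
            dev = np.linalg.norm(tf.apply(Q) - P, axis=1)
            keep = dev <= max(2.0 * dev.mean(), 1e-6)
            if keep.all() or keep.sum() < min_aligned:
                break
            P, Q = P[keep], Q[keep]
            tf = _kabsch(P, Q)
    return tf


# --------------------------------------------------------------------------
# writing
# --------------------------------------------------------------------------

def write_molecule(mol: Molecule, format: str = "SDF") -> str:
    """Serialize a molecule to SDF (V2000) or PDB (HETATM records) text."""
    fmt = format.upper()
    if fmt == "SDF":
        rd = mol.to_rdkit()
        rd.SetProp("_Name", mol.name or "molecule")
        return Chem.MolToMolBlock(rd, kekulize=True) + "$$$$\n"
    if fmt == "PDB":
        lines = []
        for i, (el, xyz) in enumerate(zip(mol.elements, mol.coords), start=1):
            name = (el + str(i))[:4]
            lines.append(
                f"HETATM{i:5d} {name:<4s}{'LIG':>4s} A{1:4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {el:>2s}")
        lines.append("END")
        return "\n".join(lines) + "\n"
    raise ValueError(f"unsupported format: {format}")


def read_sdf(text: str) -> list[Molecule]:
    """All molecules from a (multi-record) SDF string, hydrogens stripped."""
    supplier = Chem.SDMolSupplier()
    supplier.SetData(text, removeHs=True)
    out = []
    for m in supplier:
        if m is not None:
            out.append(Molecule.from_rdkit(m))
    return out


def molecule_from_smiles(smiles: str, name: str = "") -> Chem.Mol:
    """Parse a SMILES string into an RDKit molecule (no coordinates)."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"bad-smiles: {smiles!r}")
    if name:
        mol.SetProp("_Name", name)
    return mol
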