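"""Dataset curation: ligand filters, SASA burial, grouping and deduplication.

A candidate protein-ligand complex is discarded if (in this order) the
ligand is covalently linked to the protein, shares its pocket with another
ligand, contacts multiple protein entities, has fewer than 7 heavy atoms,
has molecular weight outside [140, 800] Da, or is buried less than 50% on
binding (DeltaSASA / SASA_lig). Surviving entries are grouped per protein,
restricted to the major binding site, and deduplicated by lowest R-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from rdkit import Chem
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial import cKDTree

from . import config
from .chem_io import ComplexEntry, Molecule

FILTER_REASONS = ("covalent", "multi-ligand-pocket", "multi-protein-contact",
                  "heavy-atoms", "molecular-weight", "burial", "none")


@dataclass
class FilterReport:
    entry_id: str
    verdict: str                        # keep | discard
    reason: str
    heavy_atoms: int = 0
    molecular_weight: float = 0.0
    buried_fraction: Optional[float] = None

    def __post_init__(self) -> None:
        assert (self.verdict == "discard") == (self.reason != "none")


@dataclass
class BurialResult:
    sasa_lig: float                     # A^2, ligand alone
    sasa_lig_complex: float             # A^2, ligand within the complex
    buried_fraction: float

    @property
    def delta_sasa(self) -> float:
        return self.sasa_lig - self.sasa_lig_complex


# --------------------------------------------------------------------------
# SASA (Shrake-Rupley sphere-point sampling)
# --------------------------------------------------------------------------

def _fibonacci_sphere(n: int) -> np.ndarray:
    """Near-uniform unit-sphere point set (golden-spiral lattice)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5 ** 0.5) * i
    return np.stack([np.sin(phi) * np.cos(theta),
                     np.sin(phi) * np.sin(theta),
                     np.cos(phi)], axis=1)


def shrake_rupley_sasa(coords: np.ndarray, elements: Sequence[str],
                       subset: Optional[np.ndarray] = None,
                       probe: float = config.SASA_PROBE_RADIUS,
                       n_points: int = config.SASA_N_POINTS) -> np.ndarray:
    """Per-atom solvent-accessible surface area (A^2).

    Each atom's probe-inflated sphere is sampled with ``n_points`` lattice
    points; a point is accessible if outside every neighbour's inflated
    sphere. ``subset`` restricts which atoms' areas are returned (all atoms
    still occlude).
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.array([config.VDW_RADII.get(el, config.VDW_DEFAULT)
                      for el in elements]) + probe
    sphere = _fibonacci_sphere(n_points)
    tree = cKDTree(coords)
    idx = np.arange(len(coords)) if subset is None else np.asarray(subset)
    areas = np.zeros(len(idx))
    max_r = radii.max()
    for out_i, i in enumerate(idx):
        pts = coords[i] + radii[i] * sphere
        neigh = [j for j in tree.query_ball_point(coords[i], radii[i] + max_r)
                 if j != i]
        accessible = np.ones(n_points, dtype=bool)
        for j in neigh:
            d = np.linalg.norm(pts - coords[j], axis=1)
            accessible &= d >= radii[j]
        areas[out_i] = 4.0 * np.pi * radii[i] ** 2 * accessible.mean()
    return areas


def burial_fraction(entry: ComplexEntry,
                    n_points: int = config.SASA_N_POINTS) -> BurialResult:
    """Fraction of ligand SASA buried upon binding: DeltaSASA / SASA_lig."""
    lig = entry.ligand
    sasa_alone = float(shrake_rupley_sasa(lig.coords, lig.elements,
                                          n_points=n_points).sum())
    prot_coords = entry.protein.all_coords()
    prot_elements = entry.protein.all_elements()
    heavy = [i for i, el in enumerate(prot_elements) if el != "H"]
    all_coords = np.vstack([lig.coords, prot_coords[heavy]]) \
        if len(heavy) else lig.coords
    all_elements = list(lig.elements) + [prot_elements[i] for i in heavy]
    sasa_complex = float(shrake_rupley_sasa(
        all_coords, all_elements, subset=np.arange(lig.num_atoms),
        n_points=n_points).sum())
    if sasa_alone <= 0:
        frac = 0.0
    else:
        frac = float(np.clip((sasa_alone - sasa_complex) / sasa_alone, 0.0, 1.0))
    return BurialResult(sasa_lig=sasa_alone, sasa_lig_complex=sasa_complex,
                        buried_fraction=frac)


# --------------------------------------------------------------------------
# filter cascade
# --------------------------------------------------------------------------

def _min_ligand_protein_distance(entry: ComplexEntry) -> float:
    prot = entry.protein.all_coords()
    els = entry.protein.all_elements()
    heavy = prot[[i for i, el in enumerate(els) if el != "H"]]
    if len(heavy) == 0:
        return np.inf
    tree = cKDTree(heavy)
    d, _ = tree.query(entry.ligand.coords)
    return float(np.min(d))


def filter_entry(entry: ComplexEntry,
                 other_ligand_centers: Sequence[np.ndarray] = (),
                 n_protein_entities_in_contact: Optional[int] = None,
                 burial: Optional[BurialResult] = None) -> FilterReport:
    """Apply the discard cascade; the first failing rule is the reason.

    ``other_ligand_centers`` are centres of additional candidate ligands in
    the same asymmetric unit; ``n_protein_entities_in_contact`` may be given
    directly or is derived from the entry's chains (distinct chains with any
    atom within the contact cutoff of the ligand).
    """
    lig = entry.ligand
    n_heavy = lig.num_atoms
    mw = lig.molecular_weight

    def report(reason: str, frac: Optional[float] = None) -> FilterReport:
        return FilterReport(entry_id=entry.pdb_id or lig.name,
                            verdict="discard" if reason != "none" else "keep",
                            reason=reason, heavy_atoms=n_heavy,
                            molecular_weight=mw, buried_fraction=frac)

    if _min_ligand_protein_distance(entry) < config.COVALENT_CUTOFF:
        return report("covalent")

    center = lig.centroid
    for oc in other_ligand_centers:
        if np.linalg.norm(np.asarray(oc) - center) < config.POCKET_SHARE_CUTOFF:
            return report("multi-ligand-pocket")

    if n_protein_entities_in_contact is None:
        n_protein_entities_in_contact = 0
        for ch in entry.protein.chains:
            pts = np.array([a.coord for r in ch.residues for a in r.atoms
                            if a.element != "H"])
            if len(pts) and cKDTree(pts).query(lig.coords)[0].min() \
                    < config.MULTI_PROTEIN_CONTACT:
                n_protein_entities_in_contact += 1
    if n_protein_entities_in_contact >= 2:
        return report("multi-protein-contact")

    if n_heavy < config.MIN_HEAVY_ATOMS:
        return report("heavy-atoms")

    if not (config.MW_RANGE[0] <= mw <= config.MW_RANGE[1]):
        return report("molecular-weight")

    if burial is None:
        burial = burial_fraction(entry)
    if burial.buried_fraction < config.MIN_BURIED_FRACTION:
        return report("burial", burial.buried_fraction)

    return report("none", burial.buried_fraction)


# --------------------------------------------------------------------------
# grouping / deduplication
# --------------------------------------------------------------------------

@dataclass
class ProteinLibrary:
    """Templates for one protein after curation."""

    protein_id: str
    entries: list[ComplexEntry] = field(default_factory=list)


def _canonical_smiles(mol: Molecule) -> str:
    try:
        return Chem.MolToSmiles(Chem.RemoveHs(mol.to_rdkit()))
    except Exception:
        return "|".join(sorted(mol.elements))


def group_and_select(entries: Sequence[ComplexEntry]) -> dict[str, ProteinLibrary]:
    """Group entries per protein, keep the major binding site, dedup ligands.

    Entries are grouped by UniProt id; binding sites are single-linkage
    clustered on ligand centres (8 A cutoff) and only the most populated
    cluster survives; entries sharing a canonical SMILES keep only the
    lowest-R-free structure.
    """
    groups: dict[str, list[ComplexEntry]] = {}
    for e in entries:
        if not e.uniprot_id:
            raise ValueError(f"ungroupable: entry {e.pdb_id!r} lacks a UniProt id")
        groups.setdefault(e.uniprot_id, []).append(e)

    libraries: dict[str, ProteinLibrary] = {}
    for pid, group in groups.items():
        if len(group) > 1:
            centers = np.array([e.binding_site_center for e in group])
            labels = fcluster(linkage(centers, method="single"),
                              t=config.SITE_CLUSTER_CUTOFF, criterion="distance")
            major = np.bincount(labels).argmax()
            group = [e for e, lab in zip(group, labels) if lab == major]
        by_smiles: dict[str, ComplexEntry] = {}
        for e in group:
            key = _canonical_smiles(e.ligand)
            old = by_smiles.get(key)
            if old is None or ((e.r_free if e.r_free is not None else np.inf)
                               < (old.r_free if old.r_free is not None else np.inf)):
                by_smiles[key] = e
        kept = sorted(by_smiles.values(), key=lambda e: e.pdb_id)
        libraries[pid] = ProteinLibrary(protein_id=pid, entries=kept)
    return libraries
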