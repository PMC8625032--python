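"""Deterministic synthetic fixtures: toy ligands, pockets, template libraries.

Everything here is seeded and generated at run time — no structure files
are shipped or downloaded. The toy pocket is a partial spherical shell of
carbon-like pseudo-atoms with an aperture, sized so the seed ligand sits
clash-free and roughly 70% buried; it stands in for a crystal receptor so
that superimposition, refinement, curation and evaluation can all be
exercised end to end.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem

from . import config
from .analysis import PairRecord
from .chem_io import (AtomRecord, Chain, ComplexEntry, Molecule,
                      ProteinStructure, Residue)
from .conformers import generate_conformers
from .dataset_curation import _fibonacci_sphere
from .pipeline import TemplateLibrary
from .similarity3d import _principal_axes

#: Diverse, curation-passing small molecules used as seeded fixtures.
FIXTURE_SMILES = [
    "CC(=O)Oc1ccccc1C(=O)O",                    # aspirin
    "CC(C)Cc1ccc(cc1)C(C)C(=O)O",               # ibuprofen
    "c1ccc2c(c1)cccc2OCC(O)CNC(C)C",            # propranolol-like
    "CN1CCC(CC1)Oc1ccccc1",                     # aryl piperidine ether
    "O=C(Nc1ccccc1)c1ccccc1",                   # N-phenylbenzamide
    "Clc1ccc(cc1)C(=O)NCCN",                    # chlorobenzamide amine
    "COc1ccc(cc1)CCN",                          # methoxyphenethylamine
    "CC(=O)Nc1ccc(O)cc1",                       # paracetamol
    "O=S(=O)(N)c1ccc(N)cc1",                    # sulfanilamide
    "c1ccc(cc1)c1ccccc1O",                      # phenylphenol
    "CC1CCCC(C)N1C(=O)Cc1ccccc1",               # amide piperidine
    "OCC1OC(O)C(O)C(O)C1O",                     # glucose
    "CN(C)CCc1ccc(O)cc1",                       # hordenine
    "O=C1NC(=O)c2ccccc2N1",                     # quinazolinedione
    "CCOC(=O)c1ccc(N)cc1",                      # benzocaine
    "CC(C)NCC(O)c1ccc(O)c(O)c1",                # isoprenaline
    "c1ccc2[nH]ccc2c1CCN",                      # tryptamine
    "COc1cc2c(cc1OC)CCN(C)C2",                  # tetrahydroisoquinoline
    "CC(C)(C)NCC(O)c1ccc(O)cc1",                # tert-butyl ethanolamine
    "O=C(O)c1ccccc1Nc1ccccc1",                  # fenamate scaffold
    "Cc1ccccc1NC(=O)CN1CCCC1",                  # lidocaine-like
    "c1ccc(cc1)S(=O)(=O)Nc1ccccn1",             # sulfapyridine core
    "CC(=O)c1ccc(OC(C)C)cc1",                   # aryl ketone ether
    "OC(c1ccccc1)c1ccccc1",                     # benzhydrol
    "Nc1nc(N)c2cc(ccc2n1)Cc1ccccc1",            # diaminoquinazoline
    "CCN(CC)CCNC(=O)c1ccc(N)cc1",               # procainamide
    "Oc1ccc(cc1)CCC(=O)c1ccccc1",               # chalcone-like ketone
    "CN1C(=O)N(C)c2ncn(C)c2C1=O",               # caffeine
    "O=C(CCc1ccccc1)NC1CCCCC1",                 # cyclohexyl amide
    "COc1ccccc1OCCN1CCCC1",                     # aryloxy pyrrolidine
]


def make_fixture_molecule(seed: int) -> Molecule:
    """One posed, energy-relaxed small molecule per seed (deterministic)."""
    smiles = FIXTURE_SMILES[(int(seed) - 1) % len(FIXTURE_SMILES)]
    confs = generate_conformers(smiles, max_count=1, seed=int(seed))
    mol = confs.molecule(0)
    mol.name = f"fixture{seed}"
    return mol


# --------------------------------------------------------------------------
# toy pockets
# --------------------------------------------------------------------------

def make_toy_pocket(ligand: Molecule, n_shell: int = 120,
                    aperture_deg: float = 55.0, clearance: float = 3.6,
                    symmetric_aperture: bool = True,
                    name: str = "toypocket") -> ProteinStructure:
    """Concave carbon shell molded around a ligand pose, open along z.

    For each shell direction the wall sits ``clearance`` Angstrom beyond the
    ligand's outermost atom along that ray (an offset support surface), so
    elongated ligands are cradled rather than rattling in a sphere.
    Directions within ``aperture_deg`` of the z axis are removed to create
    a solvent mouth (both poles by default, keeping the planted pose at a
    force balance along the channel). Each shell atom is the CA of a
    glycine residue so the pocket behaves as a matchable protein chain.
    Widening the aperture lowers the seed ligand's buried fraction below
    the 50% curation rule; the default leaves it well above.
    """
    center = ligand.centroid
    dirs = _fibonacci_sphere(n_shell)
    cos_ap = np.cos(np.deg2rad(aperture_deg))
    keep = dirs[:, 2] < cos_ap
    if symmetric_aperture:
        keep &= -dirs[:, 2] < cos_ap
    dirs = dirs[keep]
    rel = ligand.coords - center
    radii = (rel @ dirs.T).max(axis=0) + clearance
    pts = center + dirs * radii[:, None]
    residues = [Residue("GLY", i + 1, [AtomRecord("CA", "C", p)])
                for i, p in enumerate(pts)]
    return ProteinStructure([Chain("A", residues)], name=name)


def _place_on_scaffold(mol: Molecule, scaffold: Molecule) -> Molecule:
    """Rigidly place ``mol`` onto ``scaffold`` by matching three geometric
    anchors — centroid, first heteroatom, and the atom farthest from it —
    via least-squares superposition. Deterministic and independent of any
    similarity optimization; the heteroatom anchor resolves end-to-end
    flips that principal axes alone leave ambiguous.
    """
    from .chem_io import _kabsch

    def anchors(m: Molecule) -> np.ndarray:
        rd = m.to_rdkit()
        # the H-bond donor marks the chemically conserved end; ring
        # centroids pin the footprint of the (bicyclic) fixture ligands
        het = next((a.GetIdx() for a in rd.GetAtoms()
                    if a.GetSymbol() in ("N", "O") and a.GetTotalNumHs() > 0),
                   None)
        if het is None:
            het = next((i for i, el in enumerate(m.elements)
                        if el not in ("C", "H")), 0)
        rings = [m.coords[list(r)].mean(axis=0)
                 for r in rd.GetRingInfo().AtomRings()]
        if len(rings) >= 2:
            rings = sorted(rings,
                           key=lambda c: np.linalg.norm(c - m.coords[het]))[:2]
            return np.array([m.coords[het], rings[0], rings[1]])
        far = int(np.argmax(np.linalg.norm(m.coords - m.coords[het], axis=1)))
        return np.array([m.centroid, m.coords[het], m.coords[far]])

    tf = _kabsch(anchors(scaffold), anchors(mol))
    return mol.with_coords(tf.apply(mol.coords))


# --------------------------------------------------------------------------
# toy template libraries
# --------------------------------------------------------------------------

# Rigid fused-ring ligand family: substituents (OH, Cl, CH3, NH2) add
# features without heavy-atom rotatable bonds, so planted poses are sharp
# and pose recovery is not confounded by rotamer sampling.
_SCAFFOLD_SMILES = "Oc1ccc2cc(Cl)ccc2c1"              # chloro-naphthalenol
_TEMPLATE_VARIANTS = [
    "Oc1ccc2cc(Cl)ccc2c1",
    "Cc1ccc2ccc(O)cc2c1",                             # methyl-naphthalenol
    "Oc1ccc2ncccc2c1",                                # hydroxy-quinoline
    "Nc1ccc2cc(Cl)ccc2c1",                            # chloro-naphthylamine
    "Cc1ccc2ncc(Cl)cc2c1",                            # chloro-methylquinoline
    "Oc1ccc2cc(O)ccc2c1",                             # dihydroxy-naphthalene
]
#: Query with low 2D fingerprint similarity to the naphthalene templates
#: (Tanimoto ~0.2: different rings, different paths) yet a near-identical
#: planar fused-bicyclic footprint — the dissimilar/shared-mode regime.
#: Rigid, with hydroxyl and carbonyl anchors at opposite ends.
_DISSIMILAR_QUERY = "O=c1ccc2ccc(O)cc2o1"             # hydroxy-chromenone


@dataclass
class ToyLibrary:
    library: TemplateLibrary
    query_smiles: str
    true_pose: Molecule             # ground-truth query pose
    pocket: ProteinStructure


def make_toy_library(n_templates: int = 3,
                     query_similarity_profile: str = "identical",
                     seed: int = 0) -> ToyLibrary:
    """Seeded toy template library in one shared pocket.

    Profiles: ``identical`` (the query is template 1's own ligand),
    ``similar`` (a decorated variant of the scaffold), and
    ``dissimilar-shared-mode`` (a chemically unrelated query whose
    ground-truth pose nevertheless overlaps the template poses).
    """
    if n_templates < 1:
        raise ValueError("need at least one template")
    from .refine import IrrecoverableClashError, ReceptorGrid, local_refine

    scaffold = generate_conformers(_SCAFFOLD_SMILES, max_count=1,
                                   seed=seed + 1000).molecule(0)
    scaffold = scaffold.with_coords(scaffold.coords - scaffold.centroid)
    pocket = make_toy_pocket(scaffold, name=f"toypocket{seed}")
    grid = ReceptorGrid(pocket)

    def planted(smiles: str, embed_seed: int, name: str) -> Molecule:
        """Place a ligand on the scaffold pose, then relax it in the pocket
        (iterated to a fixed point) so the planted 'crystal' pose is an
        equilibrium of the receptor, as a crystal pose would be."""
        mol = generate_conformers(smiles, max_count=1,
                                  seed=embed_seed).molecule(0)
        posed = _place_on_scaffold(mol, scaffold)
        try:
            for _ in range(5):
                refined = local_refine(grid, posed)
                posed = refined.ligand
                if refined.displacement < 0.02:
                    break
        except IrrecoverableClashError:
            pass
        posed.name = name
        posed.smiles = smiles
        return posed

    entries = []
    for i in range(n_templates):
        smiles = _TEMPLATE_VARIANTS[i % len(_TEMPLATE_VARIANTS)]
        lig = planted(smiles, seed + i, f"TPL{i}")
        entries.append(ComplexEntry(protein=pocket, ligand=lig,
                                    pdb_id=f"TOY{i}", r_free=0.20 + 0.01 * i,
                                    uniprot_id="TOYP01"))

    if query_similarity_profile == "identical":
        query_smiles = entries[0].ligand.smiles
        true_pose = entries[0].ligand
    elif query_similarity_profile == "similar":
        query_smiles = _TEMPLATE_VARIANTS[(n_templates + 1)
                                          % len(_TEMPLATE_VARIANTS)]
        true_pose = planted(query_smiles, seed + 500, "QUERY")
    elif query_similarity_profile == "dissimilar-shared-mode":
        query_smiles = _DISSIMILAR_QUERY
        true_pose = planted(query_smiles, seed + 500, "QUERY")
    else:
        raise ValueError(f"unknown profile {query_similarity_profile!r}")

    lib = TemplateLibrary(protein_id="TOYP01", templates=entries)
    return ToyLibrary(library=lib, query_smiles=query_smiles,
                      true_pose=true_pose, pocket=pocket)


# --------------------------------------------------------------------------
# synthetic pair distributions
# --------------------------------------------------------------------------

def make_pair_distribution(bins, per_bin_counts, good_fractions,
                           seed: int = 0,
                           rmsd_good: float = config.SUCCESS_RMSD) -> list[PairRecord]:
    """Records with prescribed per-bin counts and exact good-RMSD fractions.

    ``bins`` are (lo, hi) similarity intervals; within each, ``count``
    records get similarity uniform in the bin and RMSD drawn either from
    the good range (0.5..1.8 A) or the bad range (4..8 A), with exactly
    ``round(count * fraction)`` good records.
    """
    bins, per_bin_counts, good_fractions = (list(bins), list(per_bin_counts),
                                            list(good_fractions))
    if not (len(bins) == len(per_bin_counts) == len(good_fractions)):
        raise ValueError("bins, counts and fractions must have equal length")
    rng = np.random.default_rng(seed)
    records: list[PairRecord] = []
    k = 0
    for (lo, hi), count, frac in zip(bins, per_bin_counts, good_fractions):
        if not (0.0 <= frac <= 1.0) or count < 0:
            raise ValueError("inconsistent bin specification")
        lo_f = max(lo, 0.0) if np.isfinite(lo) else 0.3
        hi_f = min(hi, 2.0) if np.isfinite(hi) else 2.0
        n_good = int(round(count * frac))
        for i in range(count):
            shafts = float(rng.uniform(lo_f, hi_f - 1e-9))
            good = i < n_good
            rmsd = float(rng.uniform(0.5, min(1.8, rmsd_good - 0.05))) if good \
                else float(rng.uniform(rmsd_good * 2, rmsd_good * 4))
            shape = min(shafts * rng.uniform(0.45, 0.55), 1.0)
            records.append(PairRecord(
                query_id=f"Q{k}", template_id=f"T{k}",
                shafts=shafts, shape=shape,
                feature=min(max(shafts - shape, 0.0), 1.0),
                tanimoto=float(rng.uniform(0.1, 0.9)), rmsd=rmsd))
            k += 1
    # shuffle deterministically so good records are not clustered by index
    order = rng.permutation(len(records))
    return [records[i] for i in order]


# --------------------------------------------------------------------------
# curation test set
# --------------------------------------------------------------------------

def make_curation_test_set(seed: int = 0):
    """Ten toy complexes, one deliberate violation of each discard rule.

    Returns ``(cases, expectations)`` where each case is a dict of
    ``filter_entry`` keyword arguments and each expectation the designed
    (verdict, reason) pair, in a fixed order: four keepers plus one
    violation of each of the six rules.
    """
    base = make_fixture_molecule(seed + 4)      # N-phenylbenzamide fixture
    pocket = make_toy_pocket(base)

    def entry(lig: Molecule, pdb_id: str, protein=None) -> ComplexEntry:
        return ComplexEntry(protein=protein or pocket, ligand=lig,
                            pdb_id=pdb_id, uniprot_id="TOYP01")

    cases = []
    expect = []

    for i in range(4):                           # clean keepers
        mol = make_fixture_molecule(seed + 4)
        mol = mol.with_coords(mol.coords)        # centred in its own pocket
        cases.append({"entry": entry(mol, f"KEEP{i}",
                                     protein=make_toy_pocket(mol))})
        expect.append(("keep", "none"))

    # (1) covalent: drag one ligand atom onto a shell atom
    mol = make_fixture_molecule(seed + 4)
    pk = make_toy_pocket(mol)
    shell0 = pk.chains[0].residues[0].atoms[0].coord
    coords = mol.coords.copy()
    coords[0] = shell0 + np.array([1.0, 0.0, 0.0])
    cases.append({"entry": entry(mol.with_coords(coords), "COV", protein=pk)})
    expect.append(("discard", "covalent"))

    # (2) second ligand centre inside the pocket
    mol = make_fixture_molecule(seed + 4)
    cases.append({"entry": entry(mol, "MULTILIG", protein=make_toy_pocket(mol)),
                  "other_ligand_centers": [mol.centroid + 2.0]})
    expect.append(("discard", "multi-ligand-pocket"))

    # (3) ligand contacting two protein entities
    mol = make_fixture_molecule(seed + 4)
    cases.append({"entry": entry(mol, "MULTIPROT", protein=make_toy_pocket(mol)),
                  "n_protein_entities_in_contact": 2})
    expect.append(("discard", "multi-protein-contact"))

    # (4) too few heavy atoms (ethanol, 3 heavy)
    small = generate_conformers("CCO", max_count=1, seed=seed).molecule(0)
    cases.append({"entry": entry(small, "SMALL", protein=make_toy_pocket(small))})
    expect.append(("discard", "heavy-atoms"))

    # (5) molecular weight out of range (heptane: 7 heavy, 100 Da)
    light = generate_conformers("CCCCCCC", max_count=1, seed=seed).molecule(0)
    cases.append({"entry": entry(light, "LIGHTMW", protein=make_toy_pocket(light))})
    expect.append(("discard", "molecular-weight"))

    # (6) under-buried: ligand shifted out through the pocket mouth
    mol = make_fixture_molecule(seed + 4)
    pk = make_toy_pocket(mol)
    out = mol.with_coords(mol.coords + np.array([0.0, 0.0, 14.0]))
    cases.append({"entry": entry(out, "EXPOSED", protein=pk)})
    expect.append(("discard", "burial"))

    return cases, expect
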