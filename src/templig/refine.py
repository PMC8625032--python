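"""Empirical protein-ligand scoring and local pose refinement.

The scoring function follows the published AutoDock Vina functional form:
five distance-dependent intermolecular terms evaluated on heavy-atom
surface distances d = r - R_i - R_j within an 8 A cutoff,

    gauss1(d)     = exp(-(d/0.5)^2)
    gauss2(d)     = exp(-((d-3)/2)^2)
    repulsion(d)  = d^2 for d < 0, else 0
    hydrophobic(d): 1 for d <= 0.5, 0 for d >= 1.5, linear between
                    (hydrophobic atom pairs only)
    hbond(d)      : 1 for d <= -0.7, 0 for d >= 0, linear between
                    (donor-acceptor pairs only)

combined with the published weights and divided by (1 + w_rot * N_rot)
where N_rot counts ligand rotatable bonds. The protein is rigid; the
ligand moves with rigid-body plus rotatable-torsion degrees of freedom.
Scores are in kcal/mol-like units; lower is better.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from scipy.optimize import minimize
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .chem_io import Molecule, ProteinStructure

#: Published term weights, in the order (gauss1, gauss2, repulsion,
#: hydrophobic, hbond); ``W_ROT`` scales the rotatable-bond denominator.
TERM_NAMES = ("gauss1", "gauss2", "repulsion", "hydrophobic", "hbond")
TERM_WEIGHTS = np.array([-0.035579, -0.005156, 0.840245, -0.035069, -0.587439])
W_ROT = 0.05846

#: Interaction radii (A) by element, after the convention used by empirical
#: docking scoring functions (larger than vdW-volume radii).
XS_RADII = {"C": 1.9, "N": 1.8, "O": 1.7, "S": 2.0, "P": 2.1,
            "F": 1.5, "Cl": 1.8, "Br": 2.0, "I": 2.2, "B": 1.9, "Se": 2.0}
XS_DEFAULT = 1.9

CUTOFF = 8.0                    # A, center-center intermolecular cutoff
CLASH_DEPTH = -1.5              # A, surface interpenetration deemed hopeless

_ROTATABLE = Chem.MolFromSmarts("[!$(*#*)&!D1]-&!@[!$(*#*)&!D1]")


class IrrecoverableClashError(RuntimeError):
    pass


@dataclass
class PoseScore:
    """Score total plus its term decomposition.

    ``weights`` are the published term weights scaled by the rotatable-bond
    factor 1/(1 + w_rot N_rot), so ``total == weights @ terms`` exactly.
    """

    total: float
    terms: np.ndarray           # raw term values, TERM_NAMES order
    weights: np.ndarray         # effective weights
    n_rot: int

    def breakdown(self) -> dict[str, float]:
        return dict(zip(TERM_NAMES, map(float, self.terms)))


@dataclass
class RefinedPose:
    ligand: Molecule
    score: PoseScore
    displacement: float         # heavy-atom RMSD from the input pose, A


# --------------------------------------------------------------------------
# atom typing
# --------------------------------------------------------------------------

def _ligand_typing(mol: Molecule):
    rd = mol.to_rdkit()
    radii = np.array([XS_RADII.get(el, XS_DEFAULT) for el in mol.elements])
    hydro = np.zeros(mol.num_atoms, dtype=bool)
    donor = np.zeros(mol.num_atoms, dtype=bool)
    accept = np.zeros(mol.num_atoms, dtype=bool)
    for atom in rd.GetAtoms():
        i, sym = atom.GetIdx(), atom.GetSymbol()
        if sym == "C":
            hydro[i] = not any(n.GetSymbol() in ("N", "O", "S", "P")
                               for n in atom.GetNeighbors())
        elif sym in ("F", "Cl", "Br", "I"):
            hydro[i] = True
        if sym in ("N", "O"):
            accept[i] = True
            if atom.GetTotalNumHs() > 0:
                donor[i] = True
    return radii, hydro, donor, accept


#: Hydroxyl/amide oxygens of Ser/Thr/Tyr donate as well as accept.
_PROTEIN_OH_NAMES = {"OG", "OG1", "OH"}


class ReceptorGrid:
    """Typed, KD-tree indexed receptor atoms for repeated scoring."""

    def __init__(self, protein: ProteinStructure):
        coords, elements, names = [], [], []
        for ch in protein.chains:
            for res in ch.residues:
                for a in res.atoms:
                    if a.element == "H":
                        continue
                    coords.append(a.coord)
                    elements.append(a.element)
                    names.append(a.name)
        self.coords = np.array(coords) if coords else np.zeros((0, 3))
        self.radii = np.array([XS_RADII.get(el, XS_DEFAULT) for el in elements])
        self.hydro = np.array([el == "C" for el in elements], dtype=bool)
        self.donor = np.array([el == "N" or nm in _PROTEIN_OH_NAMES
                               for el, nm in zip(elements, names)], dtype=bool)
        self.accept = np.array([el == "O" for el in elements], dtype=bool)
        self.tree = cKDTree(self.coords) if len(self.coords) else None

    def near(self, points: np.ndarray, margin: float = 2.0) -> np.ndarray:
        """Indices of receptor atoms within CUTOFF+margin of any query point."""
        if self.tree is None:
            return np.zeros(0, dtype=int)
        idx = self.tree.query_ball_point(points, CUTOFF + margin)
        return np.unique(np.concatenate([np.asarray(i, dtype=int) for i in idx])
                         if len(idx) else np.zeros(0, dtype=int))


def count_rotatable_bonds(mol: Molecule) -> int:
    return len(mol.to_rdkit().GetSubstructMatches(_ROTATABLE))


def _rotatable_bonds(mol: Molecule) -> list[tuple[int, int, np.ndarray]]:
    """(i, j, mask) per rotatable bond; ``mask`` marks the side rotated."""
    rd = mol.to_rdkit()
    out = []
    for i, j in rd.GetSubstructMatches(_ROTATABLE):
        em = Chem.RWMol(rd)
        em.RemoveBond(i, j)
        frags = Chem.GetMolFrags(em.GetMol(), sanitizeFrags=False)
        side_j = next(f for f in frags if j in f)
        if i in side_j:         # ring closure sneaked through; skip
            continue
        mask = np.zeros(mol.num_atoms, dtype=bool)
        mask[list(side_j)] = True
        if mask.sum() > mol.num_atoms / 2:
            mask = ~mask
            i, j = j, i
        out.append((i, j, mask))
    return out


# --------------------------------------------------------------------------
# scoring
# --------------------------------------------------------------------------

def _raw_terms(lig_coords, lig_radii, lig_hydro, lig_donor, lig_accept,
               grid: ReceptorGrid, sub: np.ndarray) -> np.ndarray:
    if len(sub) == 0:
        return np.zeros(5)
    pc = grid.coords[sub]
    r = np.linalg.norm(lig_coords[:, None, :] - pc[None, :, :], axis=-1)
    within = r < CUTOFF
    d = r - lig_radii[:, None] - grid.radii[sub][None, :]

    g1 = np.exp(-(d / 0.5) ** 2)
    g2 = np.exp(-((d - 3.0) / 2.0) ** 2)
    rep = np.where(d < 0, d * d, 0.0)
    hyd_pair = lig_hydro[:, None] & grid.hydro[sub][None, :]
    hyd = np.clip((1.5 - d) / 1.0, 0.0, 1.0) * hyd_pair
    hb_pair = (lig_donor[:, None] & grid.accept[sub][None, :]) | \
              (lig_accept[:, None] & grid.donor[sub][None, :])
    hb = np.clip(-d / 0.7, 0.0, 1.0) * hb_pair

    stack = np.stack([g1, g2, rep, hyd, hb])
    return np.array([float(np.sum(t * within)) for t in stack])


def score_pose(protein: ProteinStructure | ReceptorGrid,
               ligand: Molecule) -> PoseScore:
    """Empirical binding score of a posed ligand against a rigid receptor."""
    grid = protein if isinstance(protein, ReceptorGrid) else ReceptorGrid(protein)
    lig_radii, lig_hydro, lig_donor, lig_accept = _ligand_typing(ligand)
    n_rot = count_rotatable_bonds(ligand)
    sub = grid.near(ligand.coords)
    terms = _raw_terms(ligand.coords, lig_radii, lig_hydro, lig_donor,
                       lig_accept, grid, sub)
    eff_w = TERM_WEIGHTS / (1.0 + W_ROT * n_rot)
    return PoseScore(total=float(eff_w @ terms), terms=terms,
                     weights=eff_w, n_rot=n_rot)


# --------------------------------------------------------------------------
# local refinement
# --------------------------------------------------------------------------

class _PoseVariables:
    """Maps (translation, rotation-vector, torsions) to ligand coordinates."""

    def __init__(self, mol: Molecule):
        self.base = mol.coords.copy()
        self.center = self.base.mean(axis=0)
        self.torsions = _rotatable_bonds(mol)
        self.n_tor = len(self.torsions)
        self.n_var = 6 + self.n_tor

    def coords(self, x: np.ndarray) -> np.ndarray:
        c = self.base.copy()
        for (i, j, mask), angle in zip(self.torsions, x[6:]):
            axis = c[j] - c[i]
            norm = np.linalg.norm(axis)
            if norm < 1e-9:
                continue
            R = Rotation.from_rotvec(axis / norm * angle).as_matrix()
            c[mask] = (c[mask] - c[i]) @ R.T + c[i]
        R = Rotation.from_rotvec(x[3:6]).as_matrix()
        return (c - self.center) @ R.T + self.center + x[:3]


def local_refine(protein: ProteinStructure | ReceptorGrid,
                 start: Molecule,
                 max_translation: float = 1.5,
                 max_rotation: float = 0.4,
                 max_torsion: float = 0.6,
                 maxiter: int = 60) -> RefinedPose:
    """Locally relax a superimposed pose against a rigid receptor.

    Optimizes rigid-body plus rotatable-torsion degrees of freedom within a
    bounded neighbourhood of the start (translations up to
    ``max_translation`` A, rotations/torsions up to ``max_rotation`` /
    ``max_torsion`` rad), keeping the refinement genuinely local: the
    superimposition decides the binding mode, refinement relieves clashes.
    The refined score never exceeds the starting score. A pose still deeply
    interpenetrated after a translation-only clash-relief pre-step raises
    :class:`IrrecoverableClashError`.
    """
    grid = protein if isinstance(protein, ReceptorGrid) else ReceptorGrid(protein)
    lig_radii, lig_hydro, lig_donor, lig_accept = _ligand_typing(start)
    n_rot = count_rotatable_bonds(start)
    eff_w = TERM_WEIGHTS / (1.0 + W_ROT * n_rot)
    pv = _PoseVariables(start)
    sub = grid.near(start.coords, margin=2.0 + max_translation)

    def total(x: np.ndarray) -> float:
        terms = _raw_terms(pv.coords(x), lig_radii, lig_hydro, lig_donor,
                           lig_accept, grid, sub)
        return float(eff_w @ terms)

    def repulsion_only(t: np.ndarray) -> float:
        x = np.concatenate([t, np.zeros(3 + pv.n_tor)])
        terms = _raw_terms(pv.coords(x), lig_radii, lig_hydro, lig_donor,
                           lig_accept, grid, sub)
        return float(terms[2])

    def min_surface_distance(coords: np.ndarray) -> float:
        if len(sub) == 0:
            return np.inf
        r = np.linalg.norm(coords[:, None, :] - grid.coords[sub][None, :, :],
                           axis=-1)
        d = r - lig_radii[:, None] - grid.radii[sub][None, :]
        return float(d.min())

    x0 = np.zeros(pv.n_var)
    relief_shift = np.zeros(3)
    if repulsion_only(np.zeros(3)) > 0:
        res0 = minimize(repulsion_only, np.zeros(3), method="Powell",
                        bounds=[(-max_translation, max_translation)] * 3,
                        options={"maxiter": 40, "xtol": 1e-3})
        if res0.fun < repulsion_only(np.zeros(3)):
            relief_shift = res0.x
        relieved = pv.coords(np.concatenate([relief_shift, np.zeros(3 + pv.n_tor)]))
        s = total(np.concatenate([relief_shift, np.zeros(3 + pv.n_tor)]))
        if not np.isfinite(s) or min_surface_distance(relieved) < CLASH_DEPTH:
            raise IrrecoverableClashError(
                "irrecoverable-clash: ligand buried in receptor core")
        x0[:3] = relief_shift

    start_total = total(np.zeros(pv.n_var))
    bounds = ([(-max_translation, max_translation)] * 3 +
              [(-max_rotation, max_rotation)] * 3 +
              [(-max_torsion, max_torsion)] * pv.n_tor)
    res = minimize(total, x0, method="Powell", bounds=bounds,
                   options={"maxiter": maxiter * pv.n_var, "xtol": 1e-4,
                            "ftol": 1e-8})
    candidates = [(start_total, np.zeros(pv.n_var)), (float(res.fun), res.x)]
    if np.any(x0):
        candidates.append((total(x0), x0))
    best_total, best_x = min(candidates, key=lambda c: c[0])

    coords = pv.coords(best_x)
    terms = _raw_terms(coords, lig_radii, lig_hydro, lig_donor, lig_accept,
                       grid, sub)
    score = PoseScore(total=float(eff_w @ terms), terms=terms,
                      weights=eff_w, n_rot=n_rot)
    disp = float(np.sqrt(np.mean(np.sum((coords - start.coords) ** 2, axis=1))))
    return RefinedPose(ligand=start.with_coords(coords), score=score,
                       displacement=disp)


def bound_dock(protein: ProteinStructure | ReceptorGrid, confs,
               site_center: np.ndarray, n_starts: int = 20, seed: int = 0,
               box_edge: float = 22.0) -> RefinedPose:
    """Reference 'bound docking': seeded multi-start placement + local refinement.

    Stands in for a global docking search: conformers are dropped at random
    orientations/positions inside a box centred on the known site and each
    start is locally refined; the best-scoring pose wins.
    """
    grid = protein if isinstance(protein, ReceptorGrid) else ReceptorGrid(protein)
    rng = np.random.default_rng(seed)
    site_center = np.asarray(site_center, dtype=float)
    best: RefinedPose | None = None
    for _ in range(n_starts):
        mol = confs.molecule(int(rng.integers(len(confs))))
        R = Rotation.random(random_state=int(rng.integers(2 ** 31))).as_matrix()
        offset = rng.uniform(-box_edge / 2 + 5.0, box_edge / 2 - 5.0, size=3) * 0.3
        coords = (mol.coords - mol.centroid) @ R.T + site_center + offset
        try:
            refined = local_refine(grid, mol.with_coords(coords))
        except IrrecoverableClashError:
            continue
        if best is None or refined.score.total < best.score.total:
            best = refined
    if best is None:
        raise IrrecoverableClashError("irrecoverable-clash: no start survived")
    return best
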