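"""Hybrid 3D molecular similarity: Gaussian shape overlap + pharmacophore match.

The hybrid similarity of a query pose against a template pose is

    hybrid = shape_score + feature_score,            hybrid in [0, 2]

with ``shape_score = O_AB / max(O_AA, O_BB)`` built from first-order
atom-centred Gaussian volume overlaps, and ``feature_score`` the analogous
normalized Gaussian-kernel sum over same-kind pharmacophore feature pairs.
Both components live in [0, 1]; a molecule aligned onto itself scores
exactly 1 + 1 = 2. A score of 1.2 is the conventional cutoff separating
similar from dissimilar ligand pairs.

Superimposition maximizes the hybrid score over rigid motions of the query
using deterministic multi-start (principal-axes orientations plus the input
pose) followed by derivative-free local refinement.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
from rdkit import Chem, DataStructs
from rdkit.Chem import rdFingerprintGenerator
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from . import config
from .chem_io import Molecule, RigidTransform

FEATURE_KINDS = ("donor", "acceptor", "hydrophobe", "aromatic",
                 "positive", "negative")

# Deliberately compact SMARTS definitions; aromatic rings are handled
# geometrically (one feature per fully aromatic ring, at the centroid) and
# charge centres from formal charges.
_FEATURE_SMARTS = {
    "donor": "[#7,#8;!H0]",
    "acceptor": "[$([#8]),$([#7;v3;!$([nX3]);!$([#7;+])])]",
    "hydrophobe": "[C;!a;!$(C~[#7,#8,#9,#15,#16,#17,#35,#53])]",
}
_FEATURE_PATTERNS = {k: Chem.MolFromSmarts(s) for k, s in _FEATURE_SMARTS.items()}


@dataclass
class PharmacophoreFeature:
    kind: str
    center: np.ndarray
    radius: float = config.FEATURE_SIGMA

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        if not np.all(np.isfinite(self.center)) or self.radius <= 0:
            raise ValueError("feature needs finite center and positive radius")


@dataclass
class AlignmentResult:
    """Rigid transform of the query plus its similarity decomposition."""

    transform: RigidTransform
    shape_score: float
    feature_score: float
    query_conformer_index: int = 0

    @property
    def hybrid_sim(self) -> float:
        return self.shape_score + self.feature_score


def perceive_features(mol: Molecule) -> list[PharmacophoreFeature]:
    """Deterministic pharmacophore feature list for a posed molecule."""
    rd = mol.to_rdkit()
    feats: list[PharmacophoreFeature] = []
    for kind in ("donor", "acceptor", "hydrophobe"):
        pattern = _FEATURE_PATTERNS[kind]
        for (idx,) in rd.GetSubstructMatches(pattern):
            feats.append(PharmacophoreFeature(kind, mol.coords[idx]))
    for q, xyz in zip(mol.charges, mol.coords):
        if q > 0:
            feats.append(PharmacophoreFeature("positive", xyz))
        elif q < 0:
            feats.append(PharmacophoreFeature("negative", xyz))
    ring_info = rd.GetRingInfo()
    for ring in ring_info.AtomRings():
        if all(rd.GetAtomWithIdx(i).GetIsAromatic() for i in ring):
            center = mol.coords[list(ring)].mean(axis=0)
            feats.append(PharmacophoreFeature("aromatic", center))
    return feats


# --------------------------------------------------------------------------
# Gaussian shape overlap
# --------------------------------------------------------------------------

def _gaussian_alphas(elements) -> np.ndarray:
    """Exponents chosen so each atom Gaussian integrates to its vdW volume."""
    p = config.GAUSSIAN_P
    radii = np.array([config.VDW_RADII.get(el, config.VDW_DEFAULT)
                      for el in elements])
    return np.pi * (3.0 * p / (4.0 * np.pi * radii ** 3)) ** (2.0 / 3.0)


def _overlap_matrix_terms(alphas_a: np.ndarray, alphas_b: np.ndarray):
    p = config.GAUSSIAN_P
    s = alphas_a[:, None] + alphas_b[None, :]
    pref = p * p * (np.pi / s) ** 1.5
    k = alphas_a[:, None] * alphas_b[None, :] / s
    return pref, k


def _overlap(coords_a, coords_b, pref, k) -> float:
    d2 = np.sum((coords_a[:, None, :] - coords_b[None, :, :]) ** 2, axis=-1)
    return float(np.sum(pref * np.exp(-k * d2)))


def gaussian_shape_overlap(mol_a: Molecule, mol_b: Molecule) -> float:
    """First-order Gaussian volume overlap (A^3-scaled) of two posed molecules."""
    aa = _gaussian_alphas(mol_a.elements)
    ab = _gaussian_alphas(mol_b.elements)
    pref, k = _overlap_matrix_terms(aa, ab)
    return _overlap(mol_a.coords, mol_b.coords, pref, k)


# --------------------------------------------------------------------------
# alignment machinery
# --------------------------------------------------------------------------

class _HybridObjective:
    """Precomputed-state evaluator of the hybrid score under rigid motion.

    The query is rotated about its centroid by ``R(rotvec) @ R0`` and then
    translated; template quantities and both self-overlaps are fixed.
    """

    def __init__(self, query: Molecule, template: Molecule,
                 query_features=None, template_features=None,
                 normalization: str = "max",
                 feature_weight: float = 1.0):
        if normalization not in ("max", "tanimoto"):
            raise ValueError(f"unknown normalization {normalization!r}")
        self.normalization = normalization
        self.feature_weight = float(feature_weight)
        self.q = query.coords
        self.qc = query.coords.mean(axis=0)
        self.t_coords = template.coords
        aq = _gaussian_alphas(query.elements)
        at = _gaussian_alphas(template.elements)
        self.pref, self.k = _overlap_matrix_terms(aq, at)
        pq, kq = _overlap_matrix_terms(aq, aq)
        pt, kt = _overlap_matrix_terms(at, at)
        self.o_aa = _overlap(self.q, self.q, pq, kq)
        self.o_bb = _overlap(self.t_coords, self.t_coords, pt, kt)
        self.o_norm = max(self.o_aa, self.o_bb)

        qf = perceive_features(query) if query_features is None else query_features
        tf = perceive_features(template) if template_features is None else template_features
        self.qf_by_kind = {kind: np.array([f.center for f in qf if f.kind == kind])
                           for kind in FEATURE_KINDS}
        self.tf_by_kind = {kind: np.array([f.center for f in tf if f.kind == kind])
                           for kind in FEATURE_KINDS}
        f_aa = self._feature_sum(self.qf_by_kind, self.qf_by_kind)
        f_bb = self._feature_sum(self.tf_by_kind, self.tf_by_kind)
        self.f_norm = max(f_aa, f_bb)
        self.both_featureless = (f_aa == 0.0 and f_bb == 0.0)

    @staticmethod
    def _feature_sum(fa: dict, fb: dict) -> float:
        inv2s2 = 1.0 / (2.0 * config.FEATURE_SIGMA ** 2)
        total = 0.0
        for kind in FEATURE_KINDS:
            A, B = fa[kind], fb[kind]
            if A.size == 0 or B.size == 0:
                continue
            d2 = np.sum((A[:, None, :] - B[None, :, :]) ** 2, axis=-1)
            total += float(np.sum(np.exp(-inv2s2 * d2)))
        return total

    def scores(self, R: np.ndarray, t: np.ndarray) -> tuple[float, float]:
        """(shape_score, feature_score) for query pose x -> R(x-qc)+qc+t."""
        moved = (self.q - self.qc) @ R.T + self.qc + t
        o_ab = _overlap(moved, self.t_coords, self.pref, self.k)
        if self.normalization == "tanimoto":
            shape = o_ab / (self.o_aa + self.o_bb - o_ab)
        else:
            shape = o_ab / self.o_norm
        if self.both_featureless:
            feature = 1.0
        elif self.f_norm == 0.0:
            feature = 0.0
        else:
            fa = {kind: ((c - self.qc) @ R.T + self.qc + t if c.size else c)
                  for kind, c in self.qf_by_kind.items()}
            feature = self._feature_sum(fa, self.tf_by_kind) / self.f_norm
        return min(shape, 1.0), min(feature, 1.0)

    def hybrid(self, R: np.ndarray, t: np.ndarray) -> float:
        s, f = self.scores(R, t)
        return s + self.feature_weight * f

    def neg_hybrid_x(self, x: np.ndarray, R0: np.ndarray) -> float:
        R = Rotation.from_rotvec(x[:3]).as_matrix() @ R0
        return -self.hybrid(R, x[3:])


def _principal_axes(coords: np.ndarray) -> np.ndarray:
    """Right-handed eigenvector frame of the coordinate covariance."""
    c = coords - coords.mean(axis=0)
    cov = c.T @ c / max(len(c), 1)
    w, v = np.linalg.eigh(cov)
    v = v[:, ::-1]      # descending variance
    if np.linalg.det(v) < 0:
        v[:, 2] *= -1
    return v


def _start_rotations(query: Molecule, template: Molecule) -> list[np.ndarray]:
    """12 deterministic starts: axis pairings x proper 180-degree flips."""
    qa = _principal_axes(query.coords)
    ta = _principal_axes(template.coords)
    flips = [np.diag(d) for d in
             ([1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1])]
    perms = [np.eye(3)[list(p)] for p in ((0, 1, 2), (1, 2, 0), (2, 0, 1))]
    starts = []
    for P in perms:
        for F in flips:
            starts.append(ta @ P @ F @ qa.T)
    return starts


def align(query: Molecule, template: Molecule,
          refine_top: int = 4,
          include_input_pose: bool = True,
          query_conformer_index: int = 0,
          maxiter: int = 250,
          normalization: str = "max",
          feature_weight: float = 1.0) -> AlignmentResult:
    """Rigidly superimpose ``query`` onto the posed ``template``.

    Multi-start over principal-axes orientations (and, optionally, the
    query's input pose), coarse-scored; the best ``refine_top`` starts are
    polished with Nelder-Mead over rotation vector + translation. Fully
    deterministic. ``normalization`` selects how the shape overlap is
    scaled ("max": by the larger self-overlap, the default that puts
    self-similarity exactly at 1; "tanimoto": by O_AA + O_BB - O_AB);
    ``feature_weight`` rescales the pharmacophore term in the optimized
    objective (1.0 is the plain sum).
    """
    obj = _HybridObjective(query, template, normalization=normalization,
                           feature_weight=feature_weight)
    tc = template.coords.mean(axis=0)
    qc = obj.qc

    cands: list[tuple[float, np.ndarray, np.ndarray]] = []
    for R0 in _start_rotations(query, template):
        t0 = tc - qc
        cands.append((-obj.hybrid(R0, t0), R0, t0))
    if include_input_pose:
        cands.append((-obj.hybrid(np.eye(3), np.zeros(3)), np.eye(3), np.zeros(3)))
    cands.sort(key=lambda c: c[0])

    best_val, best_R, best_t = cands[0]
    for neg0, R0, t0 in cands[:max(refine_top, 1)]:
        res = minimize(obj.neg_hybrid_x, np.concatenate([np.zeros(3), t0]),
                       args=(R0,), method="Nelder-Mead",
                       options={"maxiter": maxiter, "xatol": 1e-4,
                                "fatol": 1e-7})
        val = res.fun
        if val < best_val:
            best_val = val
            best_R = Rotation.from_rotvec(res.x[:3]).as_matrix() @ R0
            best_t = res.x[3:]

    # polish restarts: a fresh simplex at the incumbent squeezes out the
    # last ~1e-3, making the score invariant to input-frame rotations
    for _ in range(3):
        res = minimize(obj.neg_hybrid_x, np.concatenate([np.zeros(3), best_t]),
                       args=(best_R,), method="Nelder-Mead",
                       options={"maxiter": maxiter, "xatol": 1e-6,
                                "fatol": 1e-10})
        if res.fun >= best_val - 1e-9:
            break
        best_val = res.fun
        best_R = Rotation.from_rotvec(res.x[:3]).as_matrix() @ best_R
        best_t = res.x[3:]

    shape, feature = obj.scores(best_R, best_t)
    transform = RigidTransform(best_R, qc + best_t - best_R @ qc)
    return AlignmentResult(transform=transform, shape_score=shape,
                           feature_score=feature,
                           query_conformer_index=query_conformer_index)


def rank_superimpositions(confs, template: Molecule, refine_top: int = 2,
                          maxiter: int = 250) -> list[AlignmentResult]:
    """Per-conformer alignments sorted by descending hybrid score.

    Ties break toward the lower conformer index (the sort is stable and
    conformers are visited in index order).
    """
    if len(confs) == 0:
        raise ValueError("empty conformer set")
    results = [align(confs.molecule(i), template, refine_top=refine_top,
                     include_input_pose=False, query_conformer_index=i,
                     maxiter=maxiter)
               for i in range(len(confs))]
    return sorted(results, key=lambda r: -r.hybrid_sim)


def best_superimposition(confs, template: Molecule,
                         refine_top: int = 2, maxiter: int = 250) -> AlignmentResult:
    """Best hybrid-score alignment over a conformer ensemble."""
    return rank_superimpositions(confs, template, refine_top=refine_top,
                                 maxiter=maxiter)[0]


# --------------------------------------------------------------------------
# 2D similarity
# --------------------------------------------------------------------------

_FP_GEN = rdFingerprintGenerator.GetRDKitFPGenerator(maxPath=7, fpSize=2048)


def tanimoto2d(mol_a: Molecule | Chem.Mol, mol_b: Molecule | Chem.Mol) -> float:
    """Tanimoto coefficient of 2048-bit path fingerprints (path length <= 7)."""
    rda = mol_a.to_rdkit() if isinstance(mol_a, Molecule) else mol_a
    rdb = mol_b.to_rdkit() if isinstance(mol_b, Molecule) else mol_b
    fa = _FP_GEN.GetFingerprint(rda)
    fb = _FP_GEN.GetFingerprint(rdb)
    return float(DataStructs.TanimotoSimilarity(fa, fb))
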