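"""Symmetry-aware ligand RMSD via maximum-common-substructure atom mapping.

The deviation is computed *in place* — no re-fitting rotation or translation
is applied — so it measures how far a predicted pose sits from the crystal
pose in a common receptor frame. Graph automorphisms (e.g. a flipped
para-substituted ring) are handled by minimizing over all substructure
match embeddings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFMCS

from .chem_io import ComplexEntry, Molecule, ProteinStructure, match_proteins

MIN_MCS_ATOMS = 3
MCS_TIMEOUT_S = 10
_MAX_MATCHES = 5000


class NoCommonSubstructureError(ValueError):
    pass


@dataclass
class RmsdResult:
    rmsd: float
    mapping: list[tuple[int, int]]      # (query atom, reference atom) pairs
    mapped_atoms: int
    mcs_fraction: float                 # mapped / query heavy atoms


def _same_graph_matches(pred_rd: Chem.Mol, ref_rd: Chem.Mol):
    """All automorphism-equivalent atom maps for two copies of one molecule."""
    return ref_rd.GetSubstructMatches(pred_rd, uniquify=False,
                                      maxMatches=_MAX_MATCHES,
                                      useChirality=False)


def mcs_rmsd(predicted: Molecule, reference: Molecule) -> RmsdResult:
    """Minimum in-place heavy-atom RMSD over all MCS/symmetry atom mappings.

    For two poses of the same molecule the MCS is the whole graph and only
    self-symmetry permutations are enumerated; for chemically different
    molecules (e.g. deposited ligands with missing atoms) the RMSD is taken
    over the maximum common substructure, with ``mcs_fraction`` reporting
    the mapped share of the query's heavy atoms.
    """
    pred_rd = predicted.to_rdkit()
    ref_rd = reference.to_rdkit()

    maps: list[tuple[tuple[int, ...], tuple[int, ...]]] = []
    direct = _same_graph_matches(pred_rd, ref_rd)
    if direct and len(direct[0]) == pred_rd.GetNumAtoms() == ref_rd.GetNumAtoms():
        for m in direct:
            maps.append((tuple(range(pred_rd.GetNumAtoms())), m))
    else:
        params = rdFMCS.MCSParameters()
        params.Timeout = MCS_TIMEOUT_S
        params.AtomCompareParameters.MatchValences = False
        params.BondCompareParameters.RingMatchesRingOnly = True
        res = rdFMCS.FindMCS([pred_rd, ref_rd], params)
        if res.canceled:
            warnings.warn("MCS search timed out; using partial result")
        if res.numAtoms < MIN_MCS_ATOMS or not res.smartsString:
            raise NoCommonSubstructureError(
                f"no-common-substructure: MCS has {res.numAtoms} atoms")
        patt = Chem.MolFromSmarts(res.smartsString)
        pred_matches = pred_rd.GetSubstructMatches(patt, uniquify=False,
                                                   maxMatches=_MAX_MATCHES)
        ref_matches = ref_rd.GetSubstructMatches(patt, uniquify=False,
                                                 maxMatches=_MAX_MATCHES)
        if not pred_matches or not ref_matches:
            raise NoCommonSubstructureError("no-common-substructure: no embedding")
        for pm in pred_matches:
            for rm in ref_matches:
                maps.append((pm, rm))

    best = None
    best_map = None
    for pm, rm in maps:
        d = predicted.coords[list(pm)] - reference.coords[list(rm)]
        rmsd = float(np.sqrt(np.mean(np.sum(d * d, axis=1))))
        if best is None or rmsd < best:
            best, best_map = rmsd, list(zip(pm, rm))
    return RmsdResult(rmsd=best, mapping=best_map, mapped_atoms=len(best_map),
                      mcs_fraction=len(best_map) / predicted.num_atoms)


def evaluate_prediction(predicted: Molecule, predicted_receptor: ProteinStructure,
                        reference: ComplexEntry) -> RmsdResult:
    """RMSD of a predicted pose against the crystal pose of a reference complex.

    The predicted pose's receptor is first matched onto the reference
    protein (sequence alignment + CA superposition); the resulting rigid
    transform is applied to the predicted ligand before the symmetry-aware
    in-place RMSD.
    """
    tf = match_proteins(reference.protein, predicted_receptor)
    moved = predicted.with_coords(tf.apply(predicted.coords))
    return mcs_rmsd(moved, reference.ligand)
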