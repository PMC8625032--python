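"""Conformer ensemble generation from SMILES.

Distance-geometry embedding (ETKDG) followed by MMFF94 relaxation, with
symmetry-aware RMSD de-duplication, stands in for dedicated conformer
generators. The ensemble is capped (default 200) and fully deterministic
for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem, rdMolAlign

from . import config
from .chem_io import Molecule, molecule_from_smiles


class BadSmilesError(ValueError):
    pass


class EmbedFailureError(RuntimeError):
    pass


@dataclass
class ConformerSet:
    """A parent topology plus a de-duplicated ensemble of 3D geometries."""

    parent: Molecule
    conformers: list[np.ndarray]        # each (n_heavy, 3) Angstrom
    max_count: int
    dedup_rmsd: float
    seed: int
    smiles: str = ""
    _rdkit_confs: Chem.Mol = field(default=None, repr=False)
    kept_conf_ids: list[int] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.conformers)

    def __iter__(self):
        return iter(self.conformers)

    def molecule(self, index: int) -> Molecule:
        """The parent molecule carrying conformer ``index``'s coordinates."""
        return self.parent.with_coords(self.conformers[index])


def generate_conformers(smiles: str,
                        max_count: int = config.MAX_CONFORMERS,
                        seed: int = 0,
                        dedup_rmsd: float = config.CONFORMER_DEDUP_RMSD,
                        ) -> ConformerSet:
    """Generate up to ``max_count`` 3D conformers for a SMILES string.

    Raises :class:`BadSmilesError` for unparseable input and
    :class:`EmbedFailureError` if embedding fails after retries with
    incremented seeds.
    """
    if max_count < 1:
        raise ValueError("max_count must be positive")
    try:
        mol0 = molecule_from_smiles(smiles)
    except ValueError as exc:
        raise BadSmilesError(str(exc)) from exc
    if mol0.GetNumHeavyAtoms() < 1:
        raise BadSmilesError(f"bad-smiles: no heavy atoms in {smiles!r}")

    molH = Chem.AddHs(mol0)
    cids = []
    # oversample, then de-duplicate post-relaxation: distinct embeddings can
    # collapse onto the same force-field minimum (and symmetry-equivalent
    # rotamers onto each other), so extra embeds are needed to fill the cap
    n_embed = max_count + max(max_count // 2, 10)
    for attempt in range(config.EMBED_RETRIES):
        params = AllChem.ETKDGv3()
        params.randomSeed = int(seed) + attempt
        params.useRandomCoords = attempt > 0
        cids = AllChem.EmbedMultipleConfs(molH, numConfs=n_embed, params=params)
        if len(cids) > 0:
            break
    if len(cids) == 0:
        raise EmbedFailureError(f"embed-failure: {smiles!r}")

    try:
        AllChem.MMFFOptimizeMoleculeConfs(molH, maxIters=500)
    except Exception:
        pass    # unparameterized atoms: keep raw DG geometries

    heavy = Chem.RemoveHs(molH)
    # symmetry-aware de-duplication on the relaxed geometries (embedding-time
    # pruning ignores graph automorphisms)
    kept: list[int] = []
    for cid in heavy.GetConformers():
        cid = cid.GetId()
        dup = False
        for kc in kept:
            rms = rdMolAlign.GetBestRMS(heavy, heavy, prbId=cid, refId=kc,
                                        maxMatches=2000)
            if rms < dedup_rmsd:
                dup = True
                break
        if not dup:
            kept.append(cid)
        if len(kept) >= max_count:
            break

    parent = Molecule.from_rdkit(heavy, conf_id=kept[0], smiles=smiles)
    coords = []
    for kc in kept:
        conf = heavy.GetConformer(kc)
        coords.append(np.array([[conf.GetAtomPosition(i).x,
                                 conf.GetAtomPosition(i).y,
                                 conf.GetAtomPosition(i).z]
                                for i in range(heavy.GetNumAtoms())]))
    return ConformerSet(parent=parent, conformers=coords, max_count=max_count,
                        dedup_rmsd=dedup_rmsd, seed=int(seed), smiles=smiles,
                        _rdkit_confs=heavy, kept_conf_ids=list(kept))


def conformers_to_sdf(confs: ConformerSet) -> str:
    """Multi-record SDF text, one record per conformer."""
    from .chem_io import write_molecule
    blocks = []
    for i in range(len(confs)):
        mol = confs.molecule(i)
        mol.name = f"{confs.smiles}_conf{i}"
        blocks.append(write_molecule(mol, "SDF"))
    return "".join(blocks)
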