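"""Template-guided binding-mode prediction: superimpose, refine, re-rank.

For a query ligand (SMILES) and a library of co-crystallized template
ligands sharing one receptor frame, the method runs three steps per
template:

1. **Superimposition** — generate up to 200 conformers of the query and
   keep the one whose rigid alignment onto the template ligand maximizes
   the hybrid 3D similarity (shape + pharmacophore, range [0, 2]).
2. **Local refinement** — relax the superimposed pose against the
   template's own (rigid) receptor with the empirical scoring function.
3. **Re-scoring** — rank all refined poses by the hybrid score

       hybrid_score = vina_score + alpha * similarity,  alpha = min(vina)/2

   so that, with negative binding scores, higher 3D similarity lowers
   (improves) the final score and the two contributions have comparable
   magnitude (the similarity is at most 2).

The rank-1 pose is the prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import config
from .chem_io import ComplexEntry, Molecule
from .conformers import ConformerSet, EmbedFailureError, generate_conformers
from .refine import IrrecoverableClashError, ReceptorGrid, local_refine
from .similarity3d import AlignmentResult, best_superimposition


class NoPredictionError(RuntimeError):
    pass


@dataclass
class TemplateLibrary:
    """Co-bound templates of one protein, matched into a common frame."""

    protein_id: str
    templates: list[ComplexEntry]
    alpha: Optional[float] = None       # min(vina)/2, set by a prediction run
    _grids: dict = field(default_factory=dict, repr=False)

    def __len__(self) -> int:
        return len(self.templates)

    def receptor_grid(self, index: int) -> ReceptorGrid:
        if index not in self._grids:
            self._grids[index] = ReceptorGrid(self.templates[index].protein)
        return self._grids[index]


@dataclass
class PosePrediction:
    query_id: str
    template_id: str
    ligand: Molecule                    # refined pose
    vina_score: float
    shafts_score: float                 # hybrid 3D similarity in [0, 2]
    hybrid_score: float
    rank: int = 0
    alignment: Optional[AlignmentResult] = None


def compute_alpha(vina_scores: Sequence[float]) -> float:
    """alpha = min(vina_scores) / 2; errors on an empty list."""
    scores = list(vina_scores)
    if not scores:
        raise ValueError("alpha undefined for an empty score list")
    return min(scores) / 2.0


def superimpose_query(query_confs: ConformerSet, template: ComplexEntry,
                      refine_top: int = 2) -> tuple[Molecule, AlignmentResult]:
    """Step 1: best-hybrid-similarity conformer, posed onto the template ligand."""
    aln = best_superimposition(query_confs, template.ligand,
                               refine_top=refine_top)
    conf = query_confs.molecule(aln.query_conformer_index)
    posed = conf.with_coords(aln.transform.apply(conf.coords))
    return posed, aln


def predict_pose(query_smiles: str, library: TemplateLibrary,
                 max_conformers: int = config.MAX_CONFORMERS,
                 seed: int = 0, query_id: str = "query",
                 refine_top: int = 2,
                 top_k_conformers: int = 1) -> list[PosePrediction]:
    """Run the three-step prediction against every template; rank ascending.

    Returns predictions sorted best-first by hybrid score (ties broken by
    lower binding score, then higher similarity, then template id); sets
    ``library.alpha`` from the refined binding scores of this run. By
    default only the single best-superimposed conformer per template is
    refined; ``top_k_conformers`` > 1 additionally refines the runners-up
    and keeps the best-scoring pose.
    """
    if len(library) == 0:
        raise NoPredictionError("no-prediction: empty template library")
    try:
        confs = generate_conformers(query_smiles, max_count=max_conformers,
                                    seed=seed)
    except EmbedFailureError as exc:
        raise NoPredictionError(f"no-prediction: {exc}") from exc

    from .similarity3d import rank_superimpositions

    raw: list[tuple[ComplexEntry, Molecule, AlignmentResult, float]] = []
    for ti, template in enumerate(library.templates):
        try:
            ranked = rank_superimpositions(confs, template.ligand,
                                           refine_top=refine_top)
        except ValueError:
            continue
        best = None
        for aln in ranked[:max(top_k_conformers, 1)]:
            conf = confs.molecule(aln.query_conformer_index)
            posed = conf.with_coords(aln.transform.apply(conf.coords))
            try:
                refined = local_refine(library.receptor_grid(ti), posed)
            except IrrecoverableClashError:
                continue
            if best is None or refined.score.total < best[2].score.total:
                best = (posed, aln, refined)
        if best is None:
            continue
        _, aln, refined = best
        raw.append((template, refined.ligand, aln, refined.score.total))
    if not raw:
        raise NoPredictionError("no-prediction: all templates failed")

    alpha = compute_alpha([r[3] for r in raw])
    library.alpha = alpha
    preds = [PosePrediction(query_id=query_id, template_id=t.pdb_id,
                            ligand=lig, vina_score=v,
                            shafts_score=aln.hybrid_sim,
                            hybrid_score=v + alpha * aln.hybrid_sim,
                            alignment=aln)
             for t, lig, aln, v in raw]
    return rank_predictions(preds)


def rank_predictions(preds: list[PosePrediction]) -> list[PosePrediction]:
    """Sort predictions best-first by hybrid score and assign ranks.

    Ties break toward the lower (better) binding score, then the higher
    similarity, then the template id.
    """
    preds = sorted(preds, key=lambda p: (p.hybrid_score, p.vina_score,
                                         -p.shafts_score, p.template_id))
    for i, p in enumerate(preds, start=1):
        p.rank = i
    return preds


def site_check(predicted_center: np.ndarray, reference_center: np.ndarray,
               cutoff: float = config.SITE_DISTANCE_CUTOFF) -> bool:
    """True (keep) iff the predicted site centre is within ``cutoff`` A."""
    d = np.linalg.norm(np.asarray(predicted_center, dtype=float)
                       - np.asarray(reference_center, dtype=float))
    return bool(d <= cutoff)


def success_rate(top_rank_rmsds: Sequence[float],
                 threshold: float = config.SUCCESS_RMSD) -> float:
    """Percentage of predictions whose top-ranked RMSD is strictly below
    ``threshold``."""
    rmsds = list(top_rank_rmsds)
    if not rmsds:
        raise ValueError("success rate undefined for an empty result list")
    return 100.0 * sum(r < threshold for r in rmsds) / len(rmsds)
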