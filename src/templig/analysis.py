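"""Statistical analyses over (similarity, RMSD) pair observations.

* all-vs-all intercomparison of a template library (N x (N-1) ordered
  pairs; the RMSD is always computed between two poses of the *query*
  molecule, so swapping query and template legitimately changes the value);
* coverage curves (fraction of queries with at least one template below an
  RMSD threshold, stratified by similar/dissimilar templates);
* binned low-RMSD fractions and metric-RMSD correlations;
* the nested bootstrap estimating N_min, the minimum number of randomly
  drawn templates needed so that at least one yields a good (<= 2 A) pose.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import config
from .conformers import generate_conformers
from .pipeline import TemplateLibrary, superimpose_query
from .rmsd_eval import mcs_rmsd
from .similarity3d import tanimoto2d


@dataclass
class PairRecord:
    """One ordered (query, template) observation from the intercomparison."""

    query_id: str
    template_id: str
    shafts: float               # hybrid 3D similarity, [0, 2]
    shape: float                # [0, 1]
    feature: float              # [0, 1]
    tanimoto: float             # [0, 1]
    rmsd: float                 # A, query pose vs its own crystal pose
    vina: Optional[float] = None

    def __post_init__(self) -> None:
        if self.query_id == self.template_id:
            raise ValueError("a pair must relate two different entries")


@dataclass
class BootstrapResult:
    bin_edges: tuple[float, float]      # half-open [lo, hi)
    n_min: float                        # mean over outer repetitions
    n_min_se: float
    inner_reps: int = 500
    outer_reps: int = 100


class InsufficientLibraryError(ValueError):
    pass


class UnreachableError(ValueError):
    pass


# --------------------------------------------------------------------------
# intercomparison
# --------------------------------------------------------------------------

def intercompare_all(library: TemplateLibrary, seed: int = 0,
                     max_conformers: int = 50,
                     refine_top: int = 2) -> list[PairRecord]:
    """All-vs-all intercomparison of the co-bound ligands in one library.

    For each ordered (query, template) pair of distinct entries, the query's
    conformers are superimposed onto the template's crystal pose and the
    best-similarity pose is compared (symmetry-aware, in place) with the
    query's *own* crystal pose. Yields exactly N(N-1) records.
    """
    entries = library.templates
    if len(entries) < 2:
        raise InsufficientLibraryError("insufficient-library: need >= 2 entries")

    conf_cache = {}
    records: list[PairRecord] = []
    for qi, query in enumerate(entries):
        if qi not in conf_cache:
            smiles = query.ligand.smiles
            if smiles is None:
                from rdkit import Chem
                smiles = Chem.MolToSmiles(query.ligand.to_rdkit())
            conf_cache[qi] = generate_conformers(
                smiles, max_count=max_conformers, seed=seed + qi)
        confs = conf_cache[qi]
        for ti, template in enumerate(entries):
            if ti == qi:
                continue
            posed, aln = superimpose_query(confs, template,
                                           refine_top=refine_top)
            rmsd = mcs_rmsd(posed, query.ligand).rmsd
            records.append(PairRecord(
                query_id=query.pdb_id or f"entry{qi}",
                template_id=template.pdb_id or f"entry{ti}",
                shafts=aln.hybrid_sim, shape=aln.shape_score,
                feature=aln.feature_score,
                tanimoto=tanimoto2d(query.ligand, template.ligand),
                rmsd=rmsd))
    return records


def records_to_frame(records: Sequence[PairRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records])


# --------------------------------------------------------------------------
# coverage
# --------------------------------------------------------------------------

def coverage_curve(records: Sequence[PairRecord],
                   thresholds: Sequence[float] = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0),
                   similar_cutoff: float = config.SIMILAR_CUTOFF) -> pd.DataFrame:
    """Per-threshold percentage of queries whose best template RMSD is within
    the threshold, split by similar (similarity >= cutoff) vs dissimilar
    templates. A query with no templates in a stratum contributes NA there.
    """
    if not records:
        raise ValueError("no records")
    df = records_to_frame(records)
    df["stratum"] = np.where(df["shafts"] >= similar_cutoff,
                             "similar", "dissimilar")
    rows = []
    for stratum in ("similar", "dissimilar"):
        sub = df[df["stratum"] == stratum]
        mins = sub.groupby("query_id")["rmsd"].min()
        for thr in thresholds:
            pct = float(100.0 * (mins <= thr).mean()) if len(mins) else math.nan
            rows.append({"stratum": stratum, "threshold": thr,
                         "coverage_pct": pct, "n_queries": len(mins)})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# binned statistics
# --------------------------------------------------------------------------

def similarity_bins(metric: str = "shafts") -> list[tuple[float, float]]:
    """Half-open scoring bins: open-ended ends plus 0.1-wide central bins."""
    if metric == "shafts":
        edges = [(-math.inf, 0.8)]
        edges += [(round(0.8 + 0.1 * i, 10), round(0.9 + 0.1 * i, 10))
                  for i in range(8)]
        edges.append((1.6, math.inf))
        return edges
    return [(round(0.1 * i, 10), round(0.1 * (i + 1), 10)) for i in range(10)]


def binned_stats(records: Sequence[PairRecord], metric: str = "shafts",
                 rmsd_good: float = config.SUCCESS_RMSD,
                 min_count: int = 100) -> tuple[pd.DataFrame, float]:
    """Per-bin fraction of low-RMSD (< ``rmsd_good``) cases, plus the Pearson
    correlation between the metric and the RMSD.

    Bins are half-open [lo, hi); bins with fewer than ``min_count`` records
    report a fraction of 0 with ``sufficient=False`` (the convention for
    "not enough data"). The correlation is NaN when either variable has
    zero variance.
    """
    if metric not in ("shafts", "shape", "feature", "tanimoto"):
        raise ValueError(f"unknown metric {metric!r}")
    if not records:
        raise ValueError("no records")
    df = records_to_frame(records)
    x, y = df[metric].to_numpy(), df["rmsd"].to_numpy()
    if np.std(x) == 0 or np.std(y) == 0:
        corr = math.nan
    else:
        corr = float(stats.pearsonr(x, y)[0])

    rows = []
    for lo, hi in similarity_bins(metric):
        mask = (x >= lo) & (x < hi)
        n = int(mask.sum())
        if n >= min_count:
            frac = float((y[mask] <= rmsd_good).mean())
            sufficient = True
        else:
            frac, sufficient = 0.0, False
        rows.append({"bin_lo": lo, "bin_hi": hi, "n": n,
                     "low_rmsd_fraction": frac, "sufficient": sufficient})
    return pd.DataFrame(rows), corr


# --------------------------------------------------------------------------
# minimum-template bootstrap
# --------------------------------------------------------------------------

def _nmin_one_rep(rmsds: np.ndarray, rng: np.random.Generator,
                  rmsd_good: float, inner: int) -> Optional[int]:
    """One outer repetition: smallest n with mean(min-RMSD) + SE <= cutoff."""
    m = len(rmsds)
    for n in range(1, m + 1):
        # `inner` independent draws of n records without replacement
        draws = np.argsort(rng.random((inner, m)), axis=1)[:, :n]
        mins = rmsds[draws].min(axis=1)
        mean = mins.mean()
        se = mins.std(ddof=1) / math.sqrt(inner) if inner > 1 else 0.0
        if mean + se <= rmsd_good:
            return n
    return None


def min_templates_bootstrap(records: Sequence[PairRecord] | np.ndarray,
                            rmsd_good: float = config.SUCCESS_RMSD,
                            inner: int = 500, outer: int = 100,
                            seed: int = 0,
                            bin_edges: tuple[float, float] = (-math.inf, math.inf),
                            min_records: int = 100) -> BootstrapResult:
    """Nested bootstrap of N_min for the records of one similarity bin.

    Inner loop: draw n records (without replacement), keep the minimum RMSD;
    repeat ``inner`` times; grow n from 1 until mean + SE of the minima is
    no higher than ``rmsd_good``. Outer loop: repeat the whole search
    ``outer`` times (seeds seed, seed+1, ...) and report mean and standard
    error of the ``outer`` N_min values.
    """
    if isinstance(records, np.ndarray) or (records and isinstance(records[0], (int, float, np.floating))):
        rmsds = np.asarray(records, dtype=float)
    else:
        rmsds = np.array([r.rmsd for r in records], dtype=float)
    if len(rmsds) < min_records:
        raise InsufficientLibraryError(
            f"insufficient records in bin: {len(rmsds)} < {min_records}")
    if not np.any(rmsds <= rmsd_good):
        raise UnreachableError("unreachable: no record meets the RMSD criterion")

    values = []
    for i in range(outer):
        rng = np.random.default_rng(seed + i)
        n = _nmin_one_rep(rmsds, rng, rmsd_good, inner)
        if n is None:
            raise UnreachableError(
                "unreachable: criterion unmet up to the full bin size")
        values.append(n)
    values = np.array(values, dtype=float)
    se = values.std(ddof=1) / math.sqrt(outer) if outer > 1 else 0.0
    return BootstrapResult(bin_edges=bin_edges, n_min=float(values.mean()),
                           n_min_se=float(se), inner_reps=inner,
                           outer_reps=outer)


def plot_rmsd_vs_similarity(records: Sequence[PairRecord],
                            metric: str = "shafts", ax=None):
    """Scatter of pose RMSD against a similarity metric, with the 2 A mode
    cutoff and the 1.2 similarity cutoff marked. Returns the axes."""
    import matplotlib.pyplot as plt

    df = records_to_frame(records)
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(df[metric], df["rmsd"], s=10, alpha=0.5, edgecolors="none")
    ax.axhline(config.SUCCESS_RMSD, color="grey", ls="--", lw=1)
    if metric == "shafts":
        ax.axvline(config.SIMILAR_CUTOFF, color="grey", ls=":", lw=1)
    ax.set_xlabel(f"{metric} similarity")
    ax.set_ylabel("RMSD (A)")
    return ax


def bootstrap_by_bin(records: Sequence[PairRecord],
                     rmsd_good: float = config.SUCCESS_RMSD,
                     inner: int = 500, outer: int = 100,
                     seed: int = 0, min_records: int = 100) -> pd.DataFrame:
    """Run the N_min bootstrap over every similarity bin with enough data."""
    df = records_to_frame(records)
    rows = []
    for lo, hi in similarity_bins("shafts"):
        sub = df[(df["shafts"] >= lo) & (df["shafts"] < hi)]
        if len(sub) < min_records:
            continue
        try:
            res = min_templates_bootstrap(sub["rmsd"].to_numpy(),
                                          rmsd_good=rmsd_good, inner=inner,
                                          outer=outer, seed=seed,
                                          bin_edges=(lo, hi),
                                          min_records=min_records)
        except UnreachableError:
            continue
        rows.append({"bin_lo": lo, "bin_hi": hi, "n": len(sub),
                     "n_min": res.n_min, "n_min_se": res.n_min_se})
    return pd.DataFrame(rows)
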