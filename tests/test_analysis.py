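"""Intercomparison records, coverage, binned statistics, N_min bootstrap."""

import math

import numpy as np
import pandas as pd
import pytest

from templig.analysis import (InsufficientLibraryError, PairRecord,
                              UnreachableError, binned_stats, coverage_curve,
                              intercompare_all, min_templates_bootstrap,
                              similarity_bins)
from templig.fixtures import make_pair_distribution, make_toy_library


def _rec(q, t, shafts, rmsd, **kw):
    defaults = dict(shape=min(shafts / 2, 1.0), feature=min(shafts / 2, 1.0),
                    tanimoto=0.5)
    defaults.update(kw)
    return PairRecord(query_id=q, template_id=t, shafts=shafts, rmsd=rmsd,
                      **defaults)


class TestIntercompare:
    def test_pair_count_is_n_times_n_minus_one(self):
        toy = make_toy_library(3, "similar", seed=2)
        records = intercompare_all(toy.library, seed=2, max_conformers=5)
        assert len(records) == 3 * 2
        ordered = {(r.query_id, r.template_id) for r in records}
        assert len(ordered) == 6                   # all ordered pairs distinct

    def test_single_entry_library_insufficient(self):
        toy = make_toy_library(1, "identical", seed=1)
        with pytest.raises(InsufficientLibraryError):
            intercompare_all(toy.library, seed=1)

    def test_degenerate_identical_ligand_library(self):
        """Three copies of one ligand in one pose: every comparison is a
        self-comparison, so similarity ~2 and RMSD ~0 throughout."""
        toy = make_toy_library(3, "identical", seed=5)
        lib = toy.library
        for i, entry in enumerate(lib.templates):
            entry.ligand = toy.true_pose.with_coords(toy.true_pose.coords)
            entry.ligand.smiles = toy.query_smiles
            entry.ligand.name = f"TPL{i}"
        records = intercompare_all(lib, seed=5, max_conformers=5)
        assert all(r.shafts > 1.95 for r in records)
        assert all(r.rmsd < 0.3 for r in records)


class TestCoverage:
    def test_perfect_templates_give_full_coverage(self):
        records = [_rec(f"q{i}", f"t{j}", 1.5, 0.0)
                   for i in range(3) for j in range(2)]
        df = coverage_curve(records, thresholds=(0.5, 1.0, 2.0))
        similar = df[df.stratum == "similar"]
        assert (similar.coverage_pct == 100.0).all()

    def test_hand_counted_three_query_set(self):
        minima = {"q1": 0.5, "q2": 1.5, "q3": 2.5}
        records = [_rec(q, "t", 1.5, r) for q, r in minima.items()]
        df = coverage_curve(records, thresholds=(2.0,))
        row = df[(df.stratum == "similar") & (df.threshold == 2.0)].iloc[0]
        assert row.coverage_pct == pytest.approx(100 * 2 / 3)

    def test_empty_stratum_is_nan_not_zero(self):
        records = [_rec("q", "t", 1.5, 0.5)]       # no dissimilar templates
        df = coverage_curve(records, thresholds=(2.0,))
        row = df[df.stratum == "dissimilar"].iloc[0]
        assert math.isnan(row.coverage_pct)

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(0)
        records = [_rec(f"q{i % 7}", f"t{j}", 1.5, float(rng.uniform(0, 6)))
                   for i in range(7) for j in range(5)]
        df = coverage_curve(records, thresholds=(0.5, 1.0, 2.0, 4.0, 8.0))
        sub = df[df.stratum == "similar"].sort_values("threshold")
        assert sub.coverage_pct.is_monotonic_increasing


class TestBinnedStats:
    def test_zero_variance_correlation_is_nan(self):
        records = [_rec(f"q{i}", "t", 1.0, 1.0) for i in range(5)]
        _, corr = binned_stats(records)
        assert math.isnan(corr)

    def test_planted_linear_relation_recovers_analytic_correlation(self):
        """rmsd = 6 - 2.5 * s + noise(sigma=0.5), s ~ U(0.8, 1.6):
        the population correlation is -b*sd(s)/sqrt(b^2 var(s) + sigma^2)."""
        rng = np.random.default_rng(42)
        n = 4000
        s = rng.uniform(0.8, 1.6, size=n)
        noise = rng.normal(0.0, 0.5, size=n)
        records = [_rec(f"q{i}", f"t{i}", float(si),
                        float(max(6 - 2.5 * si + ni, 0.0)))
                   for i, (si, ni) in enumerate(zip(s, noise))]
        var_s = (1.6 - 0.8) ** 2 / 12
        expected = -2.5 * math.sqrt(var_s) / math.sqrt(
            2.5 ** 2 * var_s + 0.25)
        _, corr = binned_stats(records)
        assert corr == pytest.approx(expected, abs=0.05)

    def test_sparse_bins_flagged_insufficient(self):
        records = [_rec(f"q{i}", "t", 1.05, 1.0) for i in range(150)]
        df, _ = binned_stats(records, min_count=100)
        full = df[(df.bin_lo == 1.0)].iloc[0]
        assert full.sufficient and full.low_rmsd_fraction == 1.0
        empty = df[(df.bin_lo == 1.2)].iloc[0]
        assert not empty.sufficient and empty.low_rmsd_fraction == 0.0

    def test_bin_edges_have_open_ended_tails(self):
        bins = similarity_bins("shafts")
        assert bins[0] == (-math.inf, 0.8)
        assert bins[-1] == (1.6, math.inf)
        assert len(bins) == 10


def mc_oracle_nmin(rmsds, seed, inner=500, outer=100, cutoff=2.0):
    """Independent re-implementation of the nested bootstrap using python's
    stdlib RNG and explicit loops (no shared code with the implementation)."""
    import random
    values = []
    pool = list(rmsds)
    for rep in range(outer):
        rng = random.Random(10_000 + seed + rep)
        n = 0
        while True:
            n += 1
            if n > len(pool):
                return None
            mins = [min(rng.sample(pool, n)) for _ in range(inner)]
            mean = sum(mins) / inner
            var = sum((m - mean) ** 2 for m in mins) / (inner - 1)
            se = math.sqrt(var / inner)
            if mean + se <= cutoff:
                values.append(n)
                break
    mean = sum(values) / outer
    var = sum((v - mean) ** 2 for v in values) / (outer - 1)
    return mean, math.sqrt(var / outer)


class TestBootstrap:
    def test_all_good_bin_needs_exactly_one_template(self):
        records = make_pair_distribution([(1.4, 1.5)], [120], [1.0], seed=1)
        res = min_templates_bootstrap(records, seed=1, inner=100, outer=20)
        assert res.n_min == 1.0 and res.n_min_se == 0.0

    def test_zero_good_bin_is_unreachable(self):
        records = make_pair_distribution([(0.9, 1.0)], [120], [0.0], seed=2)
        with pytest.raises(UnreachableError):
            min_templates_bootstrap(records, seed=2, inner=100, outer=5)

    def test_small_bin_rejected(self):
        records = make_pair_distribution([(1.0, 1.1)], [50], [0.5], seed=3)
        with pytest.raises(InsufficientLibraryError):
            min_templates_bootstrap(records, seed=3)

    def test_agrees_with_independent_monte_carlo_oracle(self):
        records = make_pair_distribution([(1.0, 1.1)], [150], [0.5], seed=4)
        rmsds = [r.rmsd for r in records]
        res = min_templates_bootstrap(rmsds, seed=11, inner=200, outer=30)
        oracle_mean, oracle_se = mc_oracle_nmin(rmsds, seed=99, inner=200,
                                                outer=30)
        tol = 2 * (res.n_min_se + oracle_se) + 1e-9
        assert abs(res.n_min - oracle_mean) <= max(tol, 0.5)

    def test_nmin_decreases_as_good_fraction_rises(self):
        nmins = []
        for p in (0.1, 0.3, 0.5, 0.7, 0.9):
            records = make_pair_distribution([(1.0, 1.1)], [150], [p], seed=5)
            res = min_templates_bootstrap([r.rmsd for r in records],
                                          seed=6, inner=200, outer=20)
            nmins.append(res.n_min)
        assert all(a >= b for a, b in zip(nmins, nmins[1:]))


def test_scatter_plot_helper_returns_axes():
    import matplotlib
    matplotlib.use("Agg")
    from templig.analysis import plot_rmsd_vs_similarity
    records = make_pair_distribution([(1.0, 1.1)], [30], [0.5], seed=1)
    ax = plot_rmsd_vs_similarity(records)
    assert ax.get_ylabel().startswith("RMSD")


class TestPairDistribution:
    def test_exact_good_fraction_construction(self):
        records = make_pair_distribution([(1.0, 1.1)], [100], [0.5], seed=7)
        assert len(records) == 100
        assert sum(r.rmsd <= 2.0 for r in records) == 50
        assert all(1.0 <= r.shafts < 1.1 for r in records)

    def test_inconsistent_spec_rejected(self):
        with pytest.raises(ValueError):
            make_pair_distribution([(1.0, 1.1)], [100, 200], [0.5], seed=1)
        with pytest.raises(ValueError):
            make_pair_distribution([(1.0, 1.1)], [100], [1.5], seed=1)
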