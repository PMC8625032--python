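"""Hybrid 3D similarity: features, Gaussian overlap, alignment, fingerprints."""

import itertools

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from templig import config
from templig.chem_io import Molecule
from templig.conformers import generate_conformers
from templig.fixtures import make_fixture_molecule
from templig.similarity3d import (_HybridObjective, align, best_superimposition,
                                  gaussian_shape_overlap, perceive_features,
                                  tanimoto2d)


def _mol(smiles, seed=0):
    return generate_conformers(smiles, max_count=1, seed=seed).molecule(0)


class TestFeatures:
    def test_methane_is_one_hydrophobe_only(self):
        m = Molecule(elements=["C"], coords=np.zeros((1, 3)), bonds=[])
        feats = perceive_features(m)
        assert [f.kind for f in feats] == ["hydrophobe"]

    def test_ethanol_oxygen_is_donor_and_acceptor(self):
        m = _mol("CCO")
        kinds_at_o = {f.kind for f in perceive_features(m)
                      if np.allclose(f.center, m.coords[2])}
        assert {"donor", "acceptor"} <= kinds_at_o

    def test_benzene_one_aromatic_feature_at_ring_centroid(self):
        m = _mol("c1ccccc1")
        feats = perceive_features(m)
        aromatic = [f for f in feats if f.kind == "aromatic"]
        assert len(aromatic) == 1
        np.testing.assert_allclose(aromatic[0].center, m.coords.mean(axis=0),
                                   atol=1e-9)

    def test_formal_charges_become_charge_features(self):
        m = _mol("C[N+](C)(C)C")
        kinds = [f.kind for f in perceive_features(m)]
        assert "positive" in kinds and "negative" not in kinds


class TestGaussianOverlap:
    def test_symmetric(self, aspirin):
        other = make_fixture_molecule(2)
        assert gaussian_shape_overlap(aspirin, other) == \
               pytest.approx(gaussian_shape_overlap(other, aspirin), rel=1e-12)

    def test_vanishes_at_large_separation(self, aspirin):
        far = aspirin.with_coords(aspirin.coords + 100.0)
        o_self = gaussian_shape_overlap(aspirin, aspirin)
        assert gaussian_shape_overlap(aspirin, far) < 1e-9 * o_self

    @pytest.mark.parametrize("d", [0.0, 0.5, 1.5, 3.0])
    def test_two_carbons_match_analytic_product_integral(self, d):
        a = Molecule(elements=["C"], coords=np.zeros((1, 3)), bonds=[])
        b = Molecule(elements=["C"], coords=np.array([[d, 0.0, 0.0]]), bonds=[])
        p = config.GAUSSIAN_P
        r = config.VDW_RADII["C"]
        alpha = np.pi * (3 * p / (4 * np.pi * r ** 3)) ** (2 / 3)
        expected = p * p * (np.pi / (2 * alpha)) ** 1.5 \
            * np.exp(-alpha * alpha / (2 * alpha) * d * d)
        assert gaussian_shape_overlap(a, b) == pytest.approx(expected, rel=1e-10)


class TestAlign:
    def test_self_alignment_hits_score_endpoints(self, aspirin):
        res = align(aspirin, aspirin)
        assert res.hybrid_sim == pytest.approx(2.0, abs=1e-3)
        assert res.shape_score == pytest.approx(1.0, abs=1e-3)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_recovers_random_rigid_transform(self, aspirin, seed):
        rng = np.random.default_rng(seed)
        R = Rotation.random(random_state=seed).as_matrix()
        t = rng.normal(size=3) * 5
        moved = aspirin.with_coords(aspirin.coords @ R.T + t)
        res = align(moved, aspirin)
        assert res.hybrid_sim >= 1.99
        np.testing.assert_allclose(res.transform.apply(moved.coords),
                                   aspirin.coords, atol=1e-2)

    def test_polar_vs_hydrocarbon_mimic_scores_shape_not_features(self):
        # same heavy-atom skeleton, oxygens replaced by carbons: the shapes
        # overlap almost perfectly but no feature kind is shared (every
        # carbon of the diol neighbours an oxygen, so it is not a hydrophobe)
        polar = _mol("OCCO", seed=1)
        greasy = Molecule(elements=["C"] * polar.num_atoms,
                          coords=polar.coords.copy(),
                          bonds=[(i, j, o) for i, j, o in polar.bonds])
        res = align(greasy, polar)
        assert res.shape_score > 0.85
        assert res.feature_score < 0.2

    def test_scores_within_bounds_for_arbitrary_pairs(self):
        mols = [make_fixture_molecule(s) for s in (1, 2, 3, 4)]
        for a, b in itertools.permutations(mols, 2):
            res = align(a, b)
            assert 0.0 <= res.shape_score <= 1.0
            assert 0.0 <= res.feature_score <= 1.0
            assert res.hybrid_sim == pytest.approx(
                res.shape_score + res.feature_score, abs=1e-9)

    @pytest.mark.parametrize("seed", [10, 11, 12])
    def test_rigid_invariance_of_hybrid_score(self, seed):
        a = make_fixture_molecule(5)
        b = make_fixture_molecule(6)
        base = align(a, b).hybrid_sim
        R = Rotation.random(random_state=seed).as_matrix()
        t = np.array([3.0, -1.0, 2.0])
        a2 = a.with_coords(a.coords @ R.T + t)
        b2 = b.with_coords(b.coords @ R.T + t)
        assert align(a2, b2).hybrid_sim == pytest.approx(base, abs=1e-3)

    def test_tanimoto_normalization_shares_the_self_endpoint(self, aspirin):
        res = align(aspirin, aspirin, normalization="tanimoto")
        assert res.shape_score == pytest.approx(1.0, abs=1e-3)
        # on different molecules the tanimoto scaling is the stricter one
        other = make_fixture_molecule(3)
        t = align(other, aspirin, normalization="tanimoto").shape_score
        m = align(other, aspirin).shape_score
        assert t <= m + 1e-6

    def test_optimizer_beats_exhaustive_rotation_grid(self):
        """The multi-start optimizer should not fall measurably below an
        exhaustive rigid-grid search on a small molecule (15-degree Euler
        steps x 0.25 A translation steps around the centroid match)."""
        query = _mol("CCO", seed=2)
        template = _mol("CCN", seed=3)
        opt = align(query, template).hybrid_sim

        obj = _HybridObjective(query, template)
        tc = template.coords.mean(axis=0)
        qc = query.coords.mean(axis=0)
        step = np.deg2rad(15.0)
        angles = np.arange(0, 2 * np.pi - 1e-9, step)
        half = np.arange(0, np.pi + 1e-9, step)
        shifts = [np.array(v) for v in
                  itertools.product((-0.25, 0.0, 0.25), repeat=3)]
        best = -np.inf
        for a1 in angles:
            for a2 in half:
                for a3 in angles:
                    R = Rotation.from_euler("zyz", [a1, a2, a3]).as_matrix()
                    for dv in shifts:
                        val = obj.hybrid(R, tc - qc + dv)
                        if val > best:
                            best = val
        assert opt >= best - 0.02


class TestBestSuperimposition:
    def test_single_conformer_set_returns_it(self, aspirin):
        confs = generate_conformers("CCO", max_count=1, seed=1)
        res = best_superimposition(confs, aspirin)
        assert res.query_conformer_index == 0

    def test_selects_planted_template_geometry(self):
        smiles = "CC(=O)Oc1ccccc1C(=O)O"
        template = _mol(smiles, seed=21)
        confs = generate_conformers(smiles, max_count=8, seed=21)
        res = best_superimposition(confs, template)
        assert res.hybrid_sim >= 1.95

    def test_ties_break_to_lower_conformer_index(self, aspirin):
        # benzene embeds to a single unique geometry; duplicate it manually
        confs = generate_conformers("c1ccccc1", max_count=1, seed=1)
        confs.conformers.append(confs.conformers[0].copy())
        res = best_superimposition(confs, aspirin)
        assert res.query_conformer_index == 0


class TestTanimoto:
    def test_identity_is_one(self, aspirin):
        assert tanimoto2d(aspirin, aspirin) == 1.0

    def test_matches_explicit_bitset_arithmetic(self):
        from templig.similarity3d import _FP_GEN
        a, b = _mol("CCO"), _mol("CCCO")
        bits_a = set(_FP_GEN.GetFingerprint(a.to_rdkit()).GetOnBits())
        bits_b = set(_FP_GEN.GetFingerprint(b.to_rdkit()).GetOnBits())
        expected = len(bits_a & bits_b) / len(bits_a | bits_b)
        assert tanimoto2d(a, b) == pytest.approx(expected, abs=1e-12)

    def test_symmetric(self):
        a, b = _mol("CCO"), _mol("c1ccccc1")
        assert tanimoto2d(a, b) == tanimoto2d(b, a)
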