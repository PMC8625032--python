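"""Ligand burial, the discard cascade, and per-protein grouping."""

import numpy as np
import pytest

from templig import config
from templig.chem_io import (AtomRecord, Chain, ComplexEntry, Molecule,
                             ProteinStructure, Residue)
from templig.dataset_curation import (BurialResult, burial_fraction,
                                      filter_entry, group_and_select,
                                      shrake_rupley_sasa, _fibonacci_sphere)
from templig.fixtures import (make_curation_test_set, make_fixture_molecule,
                              make_toy_pocket)


def cage_protein(radius: float, n: int = 200) -> ProteinStructure:
    pts = _fibonacci_sphere(n) * radius
    residues = [Residue("GLY", i + 1, [AtomRecord("CA", "C", p)])
                for i, p in enumerate(pts)]
    return ProteinStructure([Chain("A", residues)])


class TestSasa:
    def test_isolated_atom_equals_full_sphere(self):
        area = shrake_rupley_sasa(np.zeros((1, 3)), ["C"])[0]
        r = config.VDW_RADII["C"] + config.SASA_PROBE_RADIUS
        assert area == pytest.approx(4 * np.pi * r * r, rel=1e-9)

    def test_contact_pair_matches_spherical_cap_formula(self):
        """Two carbons at distance d: the accessible fraction of each
        probe-inflated sphere is 1 minus the buried cap area, which has the
        closed form 2*pi*r^2*(1 - cos(theta))."""
        d = 3.0
        coords = np.array([[0.0, 0.0, 0.0], [d, 0.0, 0.0]])
        r = config.VDW_RADII["C"] + config.SASA_PROBE_RADIUS
        cos_theta = d / (2 * r)             # equal radii
        cap = 2 * np.pi * r * r * (1 - cos_theta)
        expected = 4 * np.pi * r * r - cap
        areas = shrake_rupley_sasa(coords, ["C", "C"], n_points=4096)
        assert areas[0] == pytest.approx(expected, rel=0.01)

    def test_agrees_with_independent_implementation(self, aspirin):
        """Cross-check against biotite's Shrake-Rupley on the same radii."""
        biotite_struct = pytest.importorskip("biotite.structure")
        import biotite.structure as struc
        atoms = struc.AtomArray(aspirin.num_atoms)
        atoms.coord = aspirin.coords.astype(np.float32)
        atoms.element = np.array(aspirin.elements)
        atoms.atom_name = np.array([f"{el}{i}" for i, el in
                                    enumerate(aspirin.elements)])
        atoms.res_name = np.array(["LIG"] * aspirin.num_atoms)
        atoms.res_id = np.ones(aspirin.num_atoms, dtype=int)
        atoms.chain_id = np.array(["A"] * aspirin.num_atoms)
        vdw = np.array([config.VDW_RADII[el] for el in aspirin.elements])
        theirs = struc.sasa(atoms, probe_radius=config.SASA_PROBE_RADIUS,
                            vdw_radii=vdw, point_number=1000).sum()
        ours = shrake_rupley_sasa(aspirin.coords, aspirin.elements,
                                  n_points=1024).sum()
        assert ours == pytest.approx(theirs, rel=0.02)


class TestBurial:
    def test_no_protein_means_zero_burial(self, aspirin):
        empty = ProteinStructure([])
        res = burial_fraction(ComplexEntry(protein=empty, ligand=aspirin))
        assert res.buried_fraction == 0.0
        assert res.delta_sasa == pytest.approx(0.0, abs=1e-9)

    def test_closed_cage_buries_completely(self):
        lig = Molecule(elements=["C"], coords=np.zeros((1, 3)), bonds=[])
        res = burial_fraction(ComplexEntry(protein=cage_protein(4.0), ligand=lig),
                              n_points=1024)
        assert res.buried_fraction > 0.99

    def test_agrees_with_quadruple_density_recomputation(self, aspirin):
        pk = make_toy_pocket(aspirin)
        entry = ComplexEntry(protein=pk, ligand=aspirin)
        coarse = burial_fraction(entry, n_points=config.SASA_N_POINTS)
        fine = burial_fraction(entry, n_points=4 * config.SASA_N_POINTS)
        assert coarse.buried_fraction == pytest.approx(
            fine.buried_fraction, abs=0.02)

    def test_delta_sasa_identity(self, aspirin):
        entry = ComplexEntry(protein=make_toy_pocket(aspirin), ligand=aspirin)
        res = burial_fraction(entry)
        assert res.delta_sasa == pytest.approx(
            res.sasa_lig - res.sasa_lig_complex)
        assert 0.0 <= res.buried_fraction <= 1.0


class TestFilterCascade:
    def test_designed_violations_get_designed_reasons(self):
        cases, expected = make_curation_test_set(seed=0)
        for case, (verdict, reason) in zip(cases, expected):
            report = filter_entry(**case)
            assert (report.verdict, report.reason) == (verdict, reason)

    def test_first_failing_rule_wins(self):
        # ethanol is both too small and too light: heavy-atoms fires first
        from templig.conformers import generate_conformers
        small = generate_conformers("CCO", max_count=1, seed=1).molecule(0)
        entry = ComplexEntry(protein=make_toy_pocket(small), ligand=small,
                             pdb_id="X")
        assert filter_entry(entry).reason == "heavy-atoms"

    def test_report_invariant(self):
        cases, _ = make_curation_test_set(seed=1)
        for case in cases:
            rep = filter_entry(**case)
            assert (rep.verdict == "discard") == (rep.reason != "none")


class TestGrouping:
    def _entry(self, mol, pdb_id, r_free, uniprot="P1", shift=0.0):
        lig = mol.with_coords(mol.coords + shift)
        lig.smiles = mol.smiles
        return ComplexEntry(protein=ProteinStructure([]), ligand=lig,
                            pdb_id=pdb_id, r_free=r_free, uniprot_id=uniprot)

    def test_duplicate_ligand_keeps_lowest_r_free(self):
        mol = make_fixture_molecule(2)
        libs = group_and_select([self._entry(mol, "AAA", 0.25),
                                 self._entry(mol, "BBB", 0.22)])
        assert [e.pdb_id for e in libs["P1"].entries] == ["BBB"]

    def test_major_binding_site_retained(self):
        mol = make_fixture_molecule(2)
        entries = [self._entry(make_fixture_molecule(s), f"S{s}", 0.2)
                   for s in (1, 2, 3, 5, 6)]
        # minority site 40 A away with two entries
        entries += [self._entry(make_fixture_molecule(s), f"M{s}", 0.2,
                                shift=40.0) for s in (7, 8)]
        libs = group_and_select(entries)
        ids = {e.pdb_id for e in libs["P1"].entries}
        assert all(i.startswith("S") for i in ids) and len(ids) == 5

    def test_single_entry_library(self):
        libs = group_and_select([self._entry(make_fixture_molecule(3), "X", 0.3)])
        assert len(libs["P1"].entries) == 1

    def test_idempotent(self):
        entries = [self._entry(make_fixture_molecule(s), f"E{s}", 0.2 + s / 100)
                   for s in (1, 2, 3)]
        once = group_and_select(entries)
        twice = group_and_select(once["P1"].entries)
        assert [e.pdb_id for e in once["P1"].entries] == \
               [e.pdb_id for e in twice["P1"].entries]

    def test_missing_uniprot_is_ungroupable(self):
        e = self._entry(make_fixture_molecule(1), "X", 0.2, uniprot=None)
        with pytest.raises(ValueError, match="ungroupable"):
            group_and_select([e])
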