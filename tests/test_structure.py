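"""PDB I/O, Kabsch superposition and the cluster-proximity patch test."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from photoferro import (PatchTestResult, gen_toy_structure, kabsch_superpose,
                        patch_permutation_test, patch_statistic, read_pdb,
                        write_pdb)
from photoferro.structure import PDBFormatError

from oracles import exhaustive_patch_p, grid_search_rmsd


class TestPdbIO:
    def test_round_trip_three_decimals(self, toy_structure, tmp_path):
        p1, p2 = tmp_path / "a.pdb", tmp_path / "b.pdb"
        write_pdb(toy_structure, p1)
        model = read_pdb(p1)
        write_pdb(model, p2)
        assert p1.read_text() == p2.read_text()

    def test_hetatm_only_file(self, tmp_path):
        path = tmp_path / "cluster.pdb"
        path.write_text(
            "HETATM    1 FE1  SF4 A  31      10.000  11.000  12.000"
            "  1.00  0.00          FE\n"
            "HETATM    2 S2   SF4 A  31      12.000  11.000  10.000"
            "  1.00  0.00           S\nEND\n")
        model = read_pdb(path)
        assert model.ca_coords().shape == (0, 3)
        assert len(model.cluster_atoms()) == 2

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.pdb"
        path.write_text("")
        with pytest.raises(PDBFormatError, match="no ATOM"):
            read_pdb(path)

    def test_malformed_coordinate_names_line(self, tmp_path):
        path = tmp_path / "bad.pdb"
        path.write_text(
            "ATOM      1  CA  ALA A   1       1.000   2.000   3.000\n"
            "ATOM      2  CA  ALA A   2       X.XXX   2.000   3.000\n")
        with pytest.raises(PDBFormatError, match=":2:"):
            read_pdb(path)

    def test_biopython_parses_written_file_identically(self, toy_structure,
                                                       tmp_path):
        """Cross-check the fixed-column writer/reader against Bio.PDB."""
        from Bio.PDB import PDBParser
        path = tmp_path / "toy.pdb"
        write_pdb(toy_structure, path)
        bio = PDBParser(QUIET=True).get_structure("toy", str(path))
        bio_coords = np.array([a.get_coord() for a in bio.get_atoms()])
        own_coords = np.array([a.coord for a in read_pdb(path).atoms])
        assert bio_coords.shape == own_coords.shape
        assert np.allclose(bio_coords, own_coords, atol=1e-3)


class TestKabsch:
    def test_identical_sets_zero_rmsd(self, toy_structure):
        c = toy_structure.ca_coords()
        res = kabsch_superpose(c, c)
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)
        assert res.n_atoms == len(c)

    def test_rigid_invariance(self, toy_structure):
        c = toy_structure.ca_coords()
        rot = Rotation.from_euler("xyz", [1.0, -0.4, 2.5]).as_matrix()
        assert kabsch_superpose(c, c @ rot.T + [3.0, 2.0, 1.0]).rmsd <= 1e-6

    def test_rotation_is_proper_orthonormal(self, toy_structure):
        c = toy_structure.ca_coords()
        rng = np.random.default_rng(4)
        res = kabsch_superpose(c, c + rng.normal(0, 0.5, c.shape))
        r = res.rotation
        assert np.allclose(r.T @ r, np.eye(3), atol=1e-10)
        assert np.linalg.det(r) == pytest.approx(1.0, abs=1e-10)

    def test_symmetry_of_rmsd(self, toy_structure):
        c = toy_structure.ca_coords()
        rng = np.random.default_rng(11)
        d = c + rng.normal(0, 1.0, c.shape)
        assert kabsch_superpose(c, d).rmsd == \
            pytest.approx(kabsch_superpose(d, c).rmsd, abs=1e-9)

    def test_matches_grid_search_oracle_on_perturbed_set(self):
        base = np.array([[0.0, 0.0, 0.0], [3.8, 0.0, 0.0],
                         [3.8, 3.8, 0.0], [0.0, 3.8, 2.0]])
        moved = base.copy()
        moved[2, 0] += 1.0  # 1 A displacement breaks exact superposability
        rot = Rotation.from_euler("zxy", [0.7, 0.3, -1.2]).as_matrix()
        moved = moved @ rot.T + [1.0, -2.0, 0.5]
        fast = kabsch_superpose(base, moved).rmsd
        oracle = grid_search_rmsd(base, moved)
        assert fast == pytest.approx(oracle, abs=1e-3)
        assert fast <= oracle + 1e-9  # closed form is the true minimum

    def test_matches_scipy_align_vectors(self, toy_structure):
        from scipy.spatial.transform import Rotation as R
        c = toy_structure.ca_coords()
        rng = np.random.default_rng(3)
        d = c + rng.normal(0, 0.8, c.shape)
        _, rssd = R.align_vectors(d - d.mean(0), c - c.mean(0))
        assert kabsch_superpose(c, d).rmsd == \
            pytest.approx(rssd / np.sqrt(len(c)), abs=1e-8)

    def test_count_mismatch(self):
        with pytest.raises(ValueError, match="shape"):
            kabsch_superpose(np.zeros((4, 3)), np.zeros((5, 3)))

    def test_collinear_degenerate(self):
        line = np.array([[float(i), 0.0, 0.0] for i in range(5)])
        with pytest.raises(ValueError, match="collinear"):
            kabsch_superpose(line, line)


class TestPatchTest:
    def test_full_set_gives_p_one(self, toy_structure):
        res = patch_permutation_test(
            toy_structure, toy_structure.residue_numbers(), B=99, seed=0)
        assert res.p_value == 1.0

    def test_planted_patch_significant(self, toy_structure):
        res = patch_permutation_test(toy_structure, [5, 6, 7, 8], B=999,
                                     seed=1)
        assert isinstance(res, PatchTestResult)
        assert res.p_value <= 0.01
        assert res.observed < res.null_mean

    def test_seeded_reproducibility(self, toy_structure):
        a = patch_permutation_test(toy_structure, [5, 6, 7, 8], B=199, seed=9)
        b = patch_permutation_test(toy_structure, [5, 6, 7, 8], B=199, seed=9)
        assert a.p_value == b.p_value

    def test_p_value_bounds(self, toy_structure):
        res = patch_permutation_test(toy_structure, [20, 25], B=99, seed=2)
        assert 1.0 / 100.0 <= res.p_value <= 1.0

    def test_agrees_with_exhaustive_enumeration(self):
        model = gen_toy_structure(10, [3, 4, 5], seed=2)
        target = [2, 3, 9]
        exact = exhaustive_patch_p(model, target, patch_statistic)
        B = 1999
        approx = patch_permutation_test(model, target, B=B, seed=5).p_value
        margin = 4.0 * np.sqrt(exact * (1 - exact) / B) + 2.0 / B
        assert abs(approx - exact) <= margin

    def test_no_cluster_error(self, toy_structure):
        from photoferro import StructureModel
        bare = StructureModel(
            atoms=[a for a in toy_structure.atoms if a.record == "ATOM"])
        with pytest.raises(ValueError, match="cluster"):
            patch_permutation_test(bare, [5, 6, 7, 8])

    def test_minimum_set_and_permutations(self, toy_structure):
        with pytest.raises(ValueError, match="at least 2"):
            patch_permutation_test(toy_structure, [5])
        with pytest.raises(ValueError, match="99"):
            patch_permutation_test(toy_structure, [5, 6], B=10)
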