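"""Generator contracts: determinism, zero-noise exactness, planted truth."""

import numpy as np
import pytest

from photoferro import (RedoxBohrParams, RedoxScenario, TitrationScenario,
                        gen_hyperfine_series, gen_redox_dataset,
                        gen_spectra_series, gen_titration_pair,
                        gen_toy_structure, kabsch_superpose, model_potential,
                        patch_statistic, read_pdb, write_pdb)


class TestTitrationGenerator:
    def test_no_perturbation_identity(self):
        free, bound, truth = gen_titration_pair(TitrationScenario())
        assert [(p.delta_H, p.delta_N, p.height) for p in free.entries] == \
               [(p.delta_H, p.delta_N, p.height) for p in bound.entries]
        assert truth["shifted"] == truth["broadened"] == truth["doubled"] == []

    def test_seeded_determinism(self):
        sc = TitrationScenario.pioa_interface(noise_sigma_H=0.003,
                                              noise_sigma_N=0.02,
                                              noise_sigma_I=0.02, seed=7)
        a = gen_titration_pair(sc)
        b = gen_titration_pair(sc)
        for pa, pb in zip(a[1].entries, b[1].entries):
            assert (pa.delta_H, pa.delta_N, pa.height) == \
                   (pb.delta_H, pb.delta_N, pb.height)

    def test_planted_sets_recorded_in_truth(self):
        _, _, truth = gen_titration_pair(TitrationScenario.pioa_interface())
        assert truth["shifted"] == [19, 25, 34]
        assert truth["broadened"] == [4, 21, 26, 44, 53]
        assert truth["recovery_uncertain"] is False

    def test_low_effect_flag(self):
        sc = TitrationScenario(shifted={10: (0.001, 0.005)},
                               noise_sigma_H=0.01, noise_sigma_N=0.05)
        _, _, truth = gen_titration_pair(sc)
        assert truth["recovery_uncertain"] is True

    def test_planted_set_must_be_subset(self):
        with pytest.raises(ValueError, match="subset"):
            TitrationScenario(shifted={999: (0.1, 0.5)})

    def test_attenuation_range_enforced(self):
        with pytest.raises(ValueError, match="attenuation"):
            TitrationScenario(broadened={4: 1.5})

    def test_doubled_residues_emit_two_peaks(self):
        sc = TitrationScenario(doubled={30: (0.06, 0.4, 1.0)})
        _, bound, _ = gen_titration_pair(sc)
        assert len(bound.by_residue()[30]) == 2


class TestRedoxGenerator:
    def test_zero_noise_on_model_curve(self, pioc_like_scenario):
        points = gen_redox_dataset(pioc_like_scenario)[0]
        for p in points:
            assert p.e_mv == pytest.approx(
                model_potential(pioc_like_scenario.params, p.ph), abs=1e-12)
            assert p.reference == "SHE"

    def test_equal_pkas_give_constant_e_alk(self):
        sc = RedoxScenario(params=RedoxBohrParams(300.0, 6.5, 6.5),
                           noise_sigma=0.0)
        points = gen_redox_dataset(sc)[0]
        assert all(p.e_mv == pytest.approx(300.0, abs=1e-9) for p in points)

    def test_acid_alkaline_limit_difference(self):
        params = RedoxBohrParams(300.0, 5.5, 8.2)
        sc = RedoxScenario(params=params, ph_grid=np.array([2.0, 12.0]),
                           noise_sigma=0.0)
        lo, hi = gen_redox_dataset(sc)[0]
        assert lo.e_mv - hi.e_mv == pytest.approx(159.7, abs=0.1)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            RedoxScenario(params=RedoxBohrParams(300, 6, 7),
                          ph_grid=np.array([]))

    def test_replicates_differ_but_rerun_identical(self):
        sc = RedoxScenario.pioc_like(noise_sigma=3.0, n_replicates=2, seed=3)
        r1 = gen_redox_dataset(sc)
        r2 = gen_redox_dataset(sc)
        assert r1[0][0].e_mv != r1[1][0].e_mv
        assert [p.e_mv for p in r1[0]] == [p.e_mv for p in r2[0]]


class TestHyperfineGenerator:
    def test_linear_evaluation(self):
        (series,) = gen_hyperfine_series([0.05], [30.0], [288.0, 298.0, 308.0])
        assert series.shifts == pytest.approx([44.4, 44.9, 45.4])
        assert series.signal_label == "A"

    def test_zero_slope_constant(self):
        (series,) = gen_hyperfine_series([0.0], [25.0], [283.0, 298.0, 313.0])
        assert np.ptp(series.shifts) == 0.0

    def test_too_few_temperatures(self):
        with pytest.raises(ValueError, match="at least 2"):
            gen_hyperfine_series([0.05], [30.0], [298.0])

    def test_temperature_range_enforced(self):
        with pytest.raises(ValueError, match="273-330"):
            gen_hyperfine_series([0.05], [30.0], [250.0, 298.0, 320.0])

    def test_labels_in_order(self):
        series = gen_hyperfine_series([0.04] * 3, [20, 40, 60],
                                      [288, 298, 308])
        assert [s.signal_label for s in series] == ["A", "B", "C"]


class TestToyStructure:
    def test_pdb_round_trip_exact_at_3dp(self, toy_structure, tmp_path):
        path = tmp_path / "toy.pdb"
        write_pdb(toy_structure, path)
        back = read_pdb(path)
        a = np.array([at.coord for at in toy_structure.atoms])
        b = np.array([at.coord for at in back.atoms])
        assert np.allclose(a, b, atol=5e-4)

    def test_patch_closer_than_complement(self, toy_structure):
        patch = [5, 6, 7, 8]
        complement = [r for r in toy_structure.residue_numbers()
                      if r not in patch]
        assert patch_statistic(toy_structure, patch) < \
            patch_statistic(toy_structure, complement)

    def test_rigid_rotation_rmsd_zero(self, toy_structure):
        from scipy.spatial.transform import Rotation
        coords = toy_structure.ca_coords()
        rot = Rotation.from_euler("zyx", [0.4, -1.0, 2.2]).as_matrix()
        moved = coords @ rot.T + np.array([5.0, -3.0, 11.0])
        assert kabsch_superpose(coords, moved).rmsd <= 1e-6

    def test_minimum_size(self):
        with pytest.raises(ValueError, match="at least 8"):
            gen_toy_structure(5, [1, 2])

    def test_cluster_present_with_four_atoms(self, toy_structure):
        cluster = toy_structure.cluster_atoms()
        assert len(cluster) == 4
        assert {a.record for a in cluster} == {"HETATM"}


class TestSpectraGenerator:
    def test_fraction_bounds(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            gen_spectra_series([1.2])

    def test_bad_grid_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            gen_spectra_series([0.5], wavelengths=np.array([500.0, 400.0, 300.0]))

    def test_zero_noise_is_exact_mixture(self):
        from photoferro import oxidized_basis, reduced_basis
        (spec,), truth = gen_spectra_series([0.3])
        expected = 0.7 * reduced_basis().absorbance + \
            0.3 * oxidized_basis().absorbance
        assert np.allclose(spec.absorbance, expected)
        assert truth["fractions"] == [0.3]
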