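"""CSP classification: matching, thresholds, doubling, interface sets."""

import numpy as np
import pytest

from photoferro import (Peak, PeakList, TitrationScenario,
                        classify_perturbations, combined_shift,
                        detect_peak_doubling, gen_titration_pair,
                        interacting_set, match_peaks)


def _peaklist(entries, condition="free"):
    return PeakList(protein_id="p", condition=condition, entries=entries)


def _basic_entries(n=6):
    return [Peak(i + 1, "A", 7.0 + 0.1 * i, 110.0 + i, 1e5) for i in range(n)]


class TestMatchPeaks:
    def test_identical_lists_all_paired(self):
        free = _peaklist(_basic_entries())
        bound = _peaklist(_basic_entries(), "bound")
        paired = match_peaks(free, bound)
        assert (paired["status"] == "paired").all()
        assert paired["dH"].abs().max() == 0.0

    def test_absent_bound_residue_flagged_missing(self):
        free = _peaklist(_basic_entries())
        bound_entries = [p for p in _basic_entries() if p.residue_number != 4]
        bound = _peaklist(bound_entries, "bound")
        paired = match_peaks(free, bound)
        row = paired[paired.residue_number == 4].iloc[0]
        assert row["status"] == "missing"

    def test_two_bound_peaks_routed_as_doubled(self):
        free = _peaklist(_basic_entries())
        extra = _basic_entries() + [Peak(3, "A", 7.5, 118.0, 4e4)]
        bound = _peaklist(extra, "bound")
        paired = match_peaks(free, bound)
        assert paired.loc[paired.residue_number == 3, "status"].iloc[0] == \
            "doubled"

    def test_more_than_two_peaks_rejected_with_residue_named(self):
        entries = _basic_entries() + [Peak(3, "A", 7.4, 117.0, 1e4),
                                      Peak(3, "A", 7.6, 119.0, 1e4)]
        with pytest.raises(ValueError, match="3"):
            _peaklist(entries, "bound")


class TestCombinedShift:
    @pytest.mark.parametrize("dh,dn,alpha,expected", [
        (0.0, 0.0, 0.14, 0.0),
        (0.05, 0.0, 0.14, 0.05),
        (0.03, 0.2, 0.14, 0.04104),
    ])
    def test_values(self, dh, dn, alpha, expected):
        assert combined_shift(dh, dn, alpha) == pytest.approx(expected,
                                                              abs=5e-6)

    def test_sign_symmetric(self):
        assert combined_shift(-0.03, 0.2, 0.14) == \
            combined_shift(0.03, -0.2, 0.14)

    def test_alpha_must_be_positive(self):
        with pytest.raises(ValueError):
            combined_shift(0.1, 0.1, 0.0)


class TestClassifyPerturbations:
    def test_identical_lists_all_unaffected(self):
        free = _peaklist(_basic_entries())
        bound = _peaklist(_basic_entries(), "bound")
        with pytest.warns(UserWarning, match="zero variance"):
            table = classify_perturbations(match_peaks(free, bound))
        assert set(table.table["classification"]) == {"unaffected"}

    def test_pioa_fixture_recovers_planted_sets(self, pioa_fixture):
        free, bound, truth = pioa_fixture
        table = classify_perturbations(match_peaks(free, bound))
        assert sorted(table.shifted) == truth["shifted"] == [19, 25, 34]
        assert sorted(table.broadened) == truth["broadened"] == \
            [4, 21, 26, 44, 53]

    def test_lhrc_fixture_recovers_planted_sets(self, lhrc_fixture):
        free, bound, truth = lhrc_fixture
        table = classify_perturbations(match_peaks(free, bound))
        assert table.shifted >= {19, 20, 48}
        assert table.broadened >= {17, 22}
        row = table.table[table.table.residue_number == 19].iloc[0]
        assert row["classification"] == "shifted+broadened"

    def test_requires_minimum_support(self):
        free = _peaklist(_basic_entries(4))
        bound = _peaklist(_basic_entries(4), "bound")
        with pytest.raises(ValueError, match="at least 5"):
            classify_perturbations(match_peaks(free, bound))

    def test_entry_order_invariance(self, pioa_fixture):
        free, bound, _ = pioa_fixture
        shuffled = PeakList(protein_id=bound.protein_id, condition="bound",
                            entries=list(reversed(bound.entries)))
        t1 = classify_perturbations(match_peaks(free, bound))
        t2 = classify_perturbations(match_peaks(free, shuffled))
        assert t1.table["classification"].tolist() == \
            t2.table["classification"].tolist()

    def test_dn_scaling_with_alpha_compensation(self, pioa_fixture):
        free, bound, _ = pioa_fixture
        paired = match_peaks(free, bound)
        scaled = paired.copy()
        scaled["dN"] = scaled["dN"] * 4.0
        t1 = classify_perturbations(paired, alpha=0.14)
        t2 = classify_perturbations(scaled, alpha=0.14 / 4.0)
        assert np.allclose(t1.table["d_comb"].to_numpy(float),
                           t2.table["d_comb"].to_numpy(float), equal_nan=True)

    def test_planted_recovery_sensitivity_specificity(self):
        """Effects >= 3x noise: perfect recovery across 100 seeded fixtures."""
        sens = spec = 0
        total_pos = total_neg = 0
        for seed in range(1, 101):
            sc = TitrationScenario.pioa_interface(
                noise_sigma_H=0.003, noise_sigma_N=0.02, noise_sigma_I=0.02,
                seed=seed)
            free, bound, truth = gen_titration_pair(sc)
            table = classify_perturbations(match_peaks(free, bound))
            planted = set(truth["shifted"]) | set(truth["broadened"])
            called = table.shifted | table.broadened
            all_res = {p.residue_number for p in free.entries}
            sens += len(called & planted)
            total_pos += len(planted)
            spec += len((all_res - planted) - called)
            total_neg += len(all_res - planted)
        assert sens / total_pos == 1.0
        assert spec / total_neg == 1.0


class TestPeakDoubling:
    def test_no_doubling_empty(self):
        bound = _peaklist(_basic_entries(), "bound")
        assert detect_peak_doubling(bound) == {}

    def test_planted_doubling_recovered_with_ratio(self):
        doubled = {r: (0.08, 0.5, 1.0) for r in range(10, 20)}
        sc = TitrationScenario(doubled=doubled)
        _, bound, _ = gen_titration_pair(sc)
        found = detect_peak_doubling(bound)
        assert sorted(found) == list(range(10, 20))
        assert all(r == pytest.approx(1.0) for r in found.values())

    def test_pair_within_tolerance_not_reported(self):
        entries = _basic_entries() + [Peak(2, "A", 7.105, 111.0, 9e4)]
        # residue 2 sits at delta_H 7.1; second peak 0.005 ppm away
        bound = _peaklist(entries, "bound")
        assert 2 not in detect_peak_doubling(bound, tol_H=0.02, tol_N=0.1)


class TestInteractingSet:
    def test_all_unaffected_empty(self):
        free = _peaklist(_basic_entries())
        bound = _peaklist(_basic_entries(), "bound")
        with pytest.warns(UserWarning):
            table = classify_perturbations(match_peaks(free, bound))
        assert interacting_set(table) == []

    def test_pioa_union(self, pioa_fixture):
        free, bound, _ = pioa_fixture
        table = classify_perturbations(match_peaks(free, bound))
        assert interacting_set(table) == [4, 19, 21, 25, 26, 34, 44, 53]

    def test_missing_residue_included(self):
        free = _peaklist(_basic_entries(8))
        bound_entries = [p for p in _basic_entries(8) if p.residue_number != 5]
        bound = _peaklist(bound_entries, "bound")
        with pytest.warns(UserWarning):
            table = classify_perturbations(match_peaks(free, bound))
        assert 5 in interacting_set(table)
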