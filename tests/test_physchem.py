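"""Physicochemical calculations: charge, hydrophobicity, moment, composition."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from presqkit import (
    AMINO_ACIDS,
    Peptide,
    class_composition,
    frequency_matrix,
    get_scale,
    helical_wheel,
    hydrophobic_moment,
    mean_hydrophobicity,
    net_charge,
    PhyschemFeaturizer,
)
from presqkit.physchem import PKA_EMBOSS, PKA_PROTCALC, _moment

peptides_st = st.text(alphabet=AMINO_ACIDS, min_size=1, max_size=30)


class TestNetCharge:
    def test_no_ionizable_groups(self):
        assert net_charge("GGG", include_termini=False) == 0.0

    def test_single_lysine_emboss_by_hand(self):
        # N-terminus (pKa 8.6) + Lys side chain (10.8) + C-terminus (3.6) at pH 7.
        expected = (
            1 / (1 + 10 ** (7 - 8.6))
            + 1 / (1 + 10 ** (7 - 10.8))
            - 1 / (1 + 10 ** (3.6 - 7))
        )
        value = net_charge("K", PKA_EMBOSS, 7.0, include_termini=True)
        assert value == pytest.approx(expected, abs=1e-12)
        assert value == pytest.approx(0.976, abs=1e-3)

    @given(peptides_st)
    def test_monotonically_nonincreasing_in_ph(self, seq):
        grid = np.linspace(1.0, 13.0, 25)
        charges = [net_charge(seq, PKA_PROTCALC, ph) for ph in grid]
        assert all(a >= b - 1e-12 for a, b in zip(charges, charges[1:]))

    def test_ph_outside_range_rejected(self):
        with pytest.raises(ValueError):
            net_charge("K", ph=14.5)


class TestHydrophobicity:
    @pytest.mark.parametrize("aa", list(AMINO_ACIDS))
    def test_homopolymer_mean_is_scale_value(self, aa):
        scale = get_scale()
        assert mean_hydrophobicity(aa * 7) == pytest.approx(scale[aa])

    def test_two_residue_mean(self):
        assert mean_hydrophobicity("AG") == pytest.approx(0.155)

    @given(peptides_st, st.randoms(use_true_random=False))
    def test_permutation_invariance(self, seq, rnd):
        shuffled = list(seq)
        rnd.shuffle(shuffled)
        assert mean_hydrophobicity("".join(shuffled)) == pytest.approx(
            mean_hydrophobicity(seq)
        )


class TestHydrophobicMoment:
    def test_homopolymer_18mer_cancels(self):
        # 18 unit steps of 100 degrees cover all multiples of 20 degrees.
        assert hydrophobic_moment("L" * 18) == pytest.approx(0.0, abs=1e-12)

    def test_single_residue_magnitude(self):
        scale = get_scale()
        assert hydrophobic_moment("R") == pytest.approx(abs(scale["R"]))

    @given(peptides_st, st.integers(min_value=-3, max_value=3))
    def test_phase_offset_invariance(self, seq, k):
        scale = get_scale()
        values = [scale[aa] for aa in seq]
        assert _moment(values, 100.0, phase=k * 100.0) == pytest.approx(
            hydrophobic_moment(seq), abs=1e-9
        )

    def test_windowed_moment_at_least_full_moment_for_uniform(self):
        seq = "LKLLKKLLKLLKKLLKLLKKLLKL"
        assert hydrophobic_moment(seq, window=18) >= 0.0
        assert hydrophobic_moment(seq, window=100) == pytest.approx(
            hydrophobic_moment(seq)
        )


class TestHelicalWheel:
    def test_angles(self):
        wheel = helical_wheel("A" * 19)
        assert wheel[0] == (1, "A", 0.0)
        assert wheel[1][2] == pytest.approx(100.0)
        assert wheel[18][2] == pytest.approx(0.0)  # 1800 deg = 5 full turns


class TestComposition:
    def test_all_basic(self):
        comp = class_composition(["KRH"])
        assert comp["basic"] == 1.0
        assert comp["acidic"] == comp["nonpolar"] == comp["polar_uncharged"] == 0.0

    def test_hand_classified_peptide(self):
        comp = class_composition(["MASTKL"])
        assert comp["basic"] == pytest.approx(1 / 6)
        assert comp["acidic"] == 0.0
        assert comp["polar_uncharged"] == pytest.approx(2 / 6)
        assert comp["nonpolar"] == pytest.approx(3 / 6)

    @given(st.lists(peptides_st, min_size=1, max_size=6))
    def test_fractions_sum_to_one_and_duplication_invariant(self, seqs):
        comp = class_composition(seqs)
        assert sum(comp.values()) == pytest.approx(1.0, abs=1e-9)
        doubled = class_composition(seqs + seqs)
        for key in comp:
            assert doubled[key] == pytest.approx(comp[key], abs=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            class_composition([])


class TestFrequencyMatrix:
    def test_identical_peptides(self):
        fm = frequency_matrix([Peptide("a", "AR")] * 3)
        assert fm.frequencies.loc[1, "A"] == 1.0
        assert fm.frequencies.loc[2, "R"] == 1.0

    def test_split_frequencies(self):
        fm = frequency_matrix(["AR", "RA"])
        assert fm.frequencies.loc[1, "A"] == 0.5
        assert fm.frequencies.loc[2, "A"] == 0.5

    def test_coverage_counts_sequences_reaching_position(self):
        fm = frequency_matrix(["M", "MK", "MKL"], length=3)
        assert fm.coverage.tolist() == [3, 2, 1]
        covered = fm.frequencies.sum(axis=1)
        assert covered.tolist() == pytest.approx([1.0, 1.0, 1.0])

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            frequency_matrix([])


class TestFeaturizer:
    def test_feature_frame_contents(self):
        feat = PhyschemFeaturizer()
        frame = feat.fit_transform([Peptide("p1", "MASTKLR"), Peptide("p2", "GG")])
        assert list(frame.index) == ["p1", "p2"]
        assert frame.loc["p1", "length"] == 7
        assert frame.loc["p1", "net_charge"] == pytest.approx(
            net_charge("MASTKLR")
        )
        fracs = frame.filter(like="frac_").loc["p1"]
        assert fracs.sum() == pytest.approx(1.0)

    def test_sklearn_params_round_trip(self):
        from sklearn.base import clone

        feat = PhyschemFeaturizer(ph=6.0, pka="emboss")
        cloned = clone(feat)
        assert cloned.get_params()["ph"] == 6.0
        assert cloned.get_params()["pka"] == "emboss"
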