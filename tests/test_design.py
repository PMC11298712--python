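"""Consensus design, charge adjustment and variant generators."""

from itertools import combinations

import pytest

from presqkit import (
    Peptide,
    arg_scan,
    arg_series,
    charge_adjust,
    consensus_design,
    net_charge,
    point_mutants,
    suggest_charge_substitutions,
)


class TestConsensus:
    def test_unanimous_input(self):
        result = consensus_design(["MARSTKL"] * 4, length=7)
        assert result.peptide.seq == "MARSTKL"
        assert not result.per_position["tie"].any()

    def test_modal_residue_wins(self):
        result = consensus_design(["AR", "AK", "AR"], length=2)
        assert result.peptide.seq == "AR"

    def test_permutation_invariance(self):
        helices = ["MARSTKL", "MLRSTKA", "MARSVKL", "MK"]
        forward = consensus_design(helices, length=2).peptide.seq
        backward = consensus_design(helices[::-1], length=2).peptide.seq
        assert forward == backward

    def test_uncovered_position_rejected(self):
        with pytest.raises(ValueError, match="covers"):
            consensus_design(["AR", "AK"], length=5)

    def test_tie_breaks_by_overall_frequency_then_flagged(self):
        # Position 2: R and L tie 1-1; L is overall more frequent in the set.
        result = consensus_design(["AL", "ARLL"], length=2)
        assert result.peptide.seq == "AL"
        assert bool(result.per_position.loc[2, "tie"])


class TestChargeAdjust:
    def test_empty_substitutions_identity(self):
        base = Peptide("c", "MARRK")
        assert charge_adjust(base, []).seq == base.seq

    def test_arginine_replacement_reduces_count(self):
        base = Peptide("c", "RRRRR")
        adjusted = charge_adjust(base, [(1, "L"), (3, "S")])
        assert adjusted.seq == "LRSRR"
        assert adjusted.count("R") == 3

    def test_non_arginine_position_warns(self, caplog):
        base = Peptide("c", "MAK")
        with caplog.at_level("WARNING", logger="presqkit"):
            out = charge_adjust(base, [(2, "S")])
        assert out.seq == "MSK"
        assert "not R" in caplog.text

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            charge_adjust(Peptide("c", "MAK"), [(9, "S")])


class TestSuggestChargeSubstitutions:
    def test_matches_exhaustive_search(self):
        result = consensus_design(
            ["MRRSTRLKAVLG", "MRRSTRLKAVLG", "MRKSTALQAVLG"], length=12
        )
        best = suggest_charge_substitutions(result, target_charge=1.0)
        # Independent exhaustive check over every subset of arginine positions,
        # replacing each with the same runner-up residues the helper uses.
        base = result.peptide
        arg_positions = [i for i, aa in enumerate(base.seq, 1) if aa == "R"]
        repl = dict(best)

        def charge_after(subset):
            seq = list(base.seq)
            for pos in subset:
                counts = result.frequency_matrix.counts.loc[pos].drop(list("RKH"))
                seq[pos - 1] = sorted(
                    counts[counts == counts.max()].index
                )[0]
            return net_charge(Peptide("x", "".join(seq)))

        errors = {
            subset: abs(charge_after(subset) - 1.0)
            for k in range(len(arg_positions) + 1)
            for subset in combinations(arg_positions, k)
        }
        chosen = tuple(pos for pos, _ in best)
        assert errors[chosen] == pytest.approx(min(errors.values()), abs=1e-12)


class TestArgSeries:
    def test_counts_and_k_swap(self):
        base = Peptide("synTP", "MARLSRTKVAGLWRSAQLVTNAGL")
        series = arg_series(base)
        n_r = base.count("R")
        assert len(series) == n_r + 2  # nR..0R plus the K swap
        r_counts = [v.apply().count("R") for v in series[:-1]]
        assert r_counts == list(range(n_r, -1, -1))
        k_swap = series[-1].apply()
        assert k_swap.count("R") == 0
        assert k_swap.count("K") == base.count("K") + n_r
        assert all(len(v.apply()) == len(base) for v in series)

    def test_arg_free_base_rejected(self):
        with pytest.raises(ValueError):
            arg_series(Peptide("b", "MALK"))


class TestArgScan:
    def test_default_scan_on_24mer(self):
        base = Peptide("synTP_0R", "MALSTQLKVAGLWLSAQLVTNAGL".replace("K", "L"))
        variants = arg_scan(base)
        assert len(variants) == 8
        peptides = [v.apply() for v in variants]
        assert all(p.count("R") == 1 for p in peptides)
        assert len({p.seq for p in peptides}) == len(peptides)
        assert peptides[0].residue(2) == "R"

    def test_base_with_arginine_rejected(self):
        with pytest.raises(ValueError):
            arg_scan(Peptide("b", "MAR"))

    def test_duplicate_positions_rejected(self):
        with pytest.raises(ValueError):
            arg_scan(Peptide("b", "MALSTQLV"), positions=[2, 2])

    def test_empty_positions(self):
        assert arg_scan(Peptide("b", "MALSTQLV"), positions=[]) == []


class TestPointMutants:
    def test_combos(self):
        base = Peptide("FMNL", "MEAASTKLAVGLSWQLVENAGLST")
        variants = point_mutants(base, [(2, "E", "A"), (18, "E", "A")], combos=True)
        labels = [v.label for v in variants]
        assert labels == ["E2A", "E18A", "E2A/E18A"]
        double = variants[-1].apply()
        assert double.count("E") == base.count("E") - 2

    def test_singles_only(self):
        base = Peptide("FMNL", "MEAASTKLAVGLSWQLVENAGLST")
        assert len(point_mutants(base, [(2, "E", "A"), (18, "E", "A")], combos=False)) == 2

    def test_mismatched_from_residue_rejected(self):
        with pytest.raises(ValueError, match="expected"):
            point_mutants(Peptide("p", "MEA"), [(3, "E", "A")])
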