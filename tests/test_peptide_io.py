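"""Peptide validation, FASTA round-trips and matrix/table parsing."""

import numpy as np
import pytest

from presqkit import (
    AMINO_ACIDS,
    InvalidResidueError,
    Peptide,
    read_fasta,
    read_matrix,
    write_fasta,
)
from presqkit.io import read_annotations, read_overhangs


class TestPeptide:
    def test_case_folding(self):
        assert Peptide("a", "mkl").seq == "MKL"

    @pytest.mark.parametrize("bad", ["MXK", "MBL", "MZL", "MUL", "MOL", "M K"])
    def test_rejects_non_canonical(self, bad):
        with pytest.raises(InvalidResidueError) as err:
            Peptide("p", bad)
        assert err.value.position == bad.upper().index(
            next(c for c in bad.upper() if c not in AMINO_ACIDS)
        ) + 1

    def test_rejects_empty(self):
        with pytest.raises(ValueError):
            Peptide("p", "")

    def test_subsequence_is_one_based_inclusive(self):
        p = Peptide("p", "MASTKL")
        assert p.subsequence(2, 4).seq == "AST"
        assert p.residue(1) == "M"
        with pytest.raises(IndexError):
            p.subsequence(0, 3)


class TestFasta:
    def test_single_record(self, tmp_path):
        path = tmp_path / "a.fasta"
        path.write_text(">a\nMKL\n")
        assert read_fasta(path) == [Peptide("a", "MKL")]

    def test_lowercase_and_header_token(self, tmp_path):
        path = tmp_path / "a.fasta"
        path.write_text(">a some description\nmkl\n")
        [p] = read_fasta(path)
        assert p.id == "a" and p.seq == "MKL"

    def test_invalid_residue_names_id_and_position(self, tmp_path):
        path = tmp_path / "a.fasta"
        path.write_text(">ok\nMKL\n>bad\nMXL\n")
        with pytest.raises(InvalidResidueError, match="bad.*position 2"):
            read_fasta(path)

    def test_malformed_file(self, tmp_path):
        path = tmp_path / "a.fasta"
        path.write_text("MKL\n>a\nMKL\n")
        with pytest.raises(ValueError, match="line 1"):
            read_fasta(path)

    def test_round_trip_preserves_order_and_sequences(self, tmp_path, rng):
        peptides = [
            Peptide(f"p{i}", "".join(rng.choice(list(AMINO_ACIDS), size=n)))
            for i, n in enumerate([1, 7, 61, 200])
        ]
        path = tmp_path / "rt.fasta"
        write_fasta(peptides, path)
        assert read_fasta(path) == peptides


class TestSubstitutionMatrix:
    def test_shipped_blosum30_literal_entries(self, blosum30):
        # Values read by eye from the shipped NCBI matrix file.
        assert blosum30.score("A", "A") == 4
        assert blosum30.score("W", "W") == 20
        assert blosum30.score("C", "D") == -3

    def test_symmetry_over_all_pairs(self, blosum30):
        for a in AMINO_ACIDS:
            for b in AMINO_ACIDS:
                assert blosum30.score(a, b) == blosum30.score(b, a)

    def test_matches_independent_distribution(self, blosum30):
        # biotite ships its own copy of the published BLOSUM30.
        from biotite.sequence import ProteinSequence
        from biotite.sequence.align import SubstitutionMatrix as BtMatrix

        alphabet = ProteinSequence.alphabet
        bt = BtMatrix(alphabet, alphabet, "BLOSUM30")
        for a in AMINO_ACIDS:
            for b in AMINO_ACIDS:
                assert blosum30.score(a, b) == bt.get_score(a, b)

    def test_comment_lines_ignored(self, tmp_path):
        path = tmp_path / "m.txt"
        path.write_text(
            "# a comment\n   " + "  ".join(AMINO_ACIDS) + "\n"
            + "\n".join(
                aa + " " + " ".join("1" if aa == bb else "0" for bb in AMINO_ACIDS)
                for aa in AMINO_ACIDS
            )
            + "\n"
        )
        m = read_matrix(path)
        assert m.score("A", "A") == 1 and m.score("A", "C") == 0

    def test_asymmetric_matrix_rejected(self, tmp_path):
        rows = []
        for i, aa in enumerate(AMINO_ACIDS):
            values = ["0"] * len(AMINO_ACIDS)
            values[i] = "1"
            rows.append(aa + " " + " ".join(values))
        # Break symmetry at (A, C) only.
        rows[0] = "A 1 5 " + " ".join(["0"] * (len(AMINO_ACIDS) - 2))
        path = tmp_path / "asym.txt"
        path.write_text("   " + "  ".join(AMINO_ACIDS) + "\n" + "\n".join(rows) + "\n")
        with pytest.raises(ValueError, match="asymmetric"):
            read_matrix(path)

    def test_missing_residue_rejected(self, tmp_path):
        sub = AMINO_ACIDS[:-1]  # drop Y
        path = tmp_path / "partial.txt"
        path.write_text(
            "   " + "  ".join(sub) + "\n"
            + "\n".join(
                aa + " " + " ".join("1" if aa == bb else "0" for bb in sub)
                for aa in sub
            )
            + "\n"
        )
        with pytest.raises(ValueError, match="missing"):
            read_matrix(path)


class TestTables:
    def test_annotation_validation(self, tmp_path):
        path = tmp_path / "ann.tsv"
        path.write_text(
            "# comment\nprotein_id\torganelle\ttp_end\thelix_segments\thelix_class\n"
            "P1\tmito\t40\t5-20\tsingle_alpha\n"
        )
        df = read_annotations(path)
        assert df.loc[0, "tp_end"] == 40

    @pytest.mark.parametrize(
        "row",
        [
            "P1\tnucleus\t40\t\tnone",          # unknown organelle
            "P1\tmito\t40\t5-50\tsingle_alpha",  # segment beyond tp_end
            "P1\tmito\t40\t5-20;10-30\tmulti_alpha",  # overlapping segments
            "P1\tmito\t0\t\tnone",              # tp_end < 1
        ],
    )
    def test_annotation_rejects_bad_rows(self, tmp_path, row):
        path = tmp_path / "ann.tsv"
        path.write_text(
            "protein_id\torganelle\ttp_end\thelix_segments\thelix_class\n" + row + "\n"
        )
        with pytest.raises(ValueError):
            read_annotations(path)

    def test_overhang_validation(self, tmp_path):
        path = tmp_path / "ov.tsv"
        path.write_text("query_id\thomolog_id\tquery_aln_start\nQ1\tH1\t0\n")
        with pytest.raises(ValueError, match="query_aln_start"):
            read_overhangs(path)
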