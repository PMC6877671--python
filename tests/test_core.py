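"""Ligand table ingest, set subtraction and the nesting relation."""

import pytest
from hypothesis import given, settings, strategies as st

from episelect.core import (HlaClass, LigandRecord, LigandSet, SubtractMode,
                            Tissue, is_nested, normalize_allele,
                            read_ligand_table, subtract, validate_peptide,
                            write_ligand_table)
from episelect.errors import AlphabetError, FormatError

from conftest import write_tsv

peptides = st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=12)


class TestIngest:
    def test_well_formed_table(self, tmp_path):
        path = write_tsv(tmp_path / "t.tsv", ["sequence", "patient", "tissue"],
                         [["ALKDYTREW", "P1", "tumor"],
                          ["GAKLMNPQR", "P1", "tumor"],
                          ["KLMNPQRST", "P1", "tumor"]])
        ls, log = read_ligand_table(path, HlaClass.I)
        assert len(ls) == 3 and log.n_kept == 3
        assert ls.get("ALKDYTREW").tissue is Tissue.TUMOR

    def test_out_of_range_lengths_dropped_and_counted(self, tmp_path):
        path = write_tsv(tmp_path / "t.tsv", ["sequence", "patient", "tissue"],
                         [["ALKDYTR", "P1", "tumor"],          # 7-mer
                          ["ALKDYTREWALKD", "P1", "tumor"],    # 13-mer
                          ["ALKDYTREW", "P1", "tumor"]])
        ls, log = read_ligand_table(path, HlaClass.I)
        assert len(ls) == 1
        assert log.n_length_dropped == 2

    def test_class_ii_range_is_9_to_25(self, tmp_path):
        path = write_tsv(tmp_path / "t.tsv", ["sequence", "patient", "tissue"],
                         [["ALKDYTRE", "P1", "tumor"],          # 8-mer: too short
                          ["NPPSMVAAGSVVAAV", "P1", "tumor"]])  # 15-mer ok
        ls, log = read_ligand_table(path, HlaClass.II)
        assert ls.sequences() == ["NPPSMVAAGSVVAAV"]
        assert log.n_length_dropped == 1

    def test_non_alphabet_row_rejected_not_fatal(self, tmp_path):
        path = write_tsv(tmp_path / "t.tsv", ["sequence", "patient", "tissue"],
                         [["ALX9KTREW", "P1", "tumor"],
                          ["ALKDYTREW", "P1", "tumor"]])
        ls, log = read_ligand_table(path, HlaClass.I)
        assert len(ls) == 1
        assert log.n_alphabet_rejected == 1
        assert log.rejected_rows[0][1] == "ALX9KTREW"

    def test_missing_column_names_the_column(self, tmp_path):
        path = write_tsv(tmp_path / "t.tsv", ["sequence", "patient"],
                         [["ALKDYTREW", "P1"]])
        with pytest.raises(FormatError, match="tissue"):
            read_ligand_table(path, HlaClass.I)

    def test_comma_dialect_autodetected(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("sequence,patient,tissue\nALKDYTREW,P1,NML\n")
        ls, _ = read_ligand_table(path, HlaClass.I)
        assert ls.get("ALKDYTREW").tissue is Tissue.NML

    def test_dedup_keeps_first_metadata_and_counts_multiplicity(self, tmp_path):
        path = write_tsv(tmp_path / "t.tsv", ["sequence", "patient", "tissue"],
                         [["ALKDYTREW", "P1", "tumor"],
                          ["alkdytrew", "P2", "NML"]])
        ls, log = read_ligand_table(path, HlaClass.I)
        assert len(ls) == 1 and log.n_duplicates == 1
        assert ls.get("ALKDYTREW").patient_id == "P1"
        assert ls.multiplicity["ALKDYTREW"] == 2

    def test_write_read_roundtrip(self, tmp_path):
        ls = LigandSet.from_sequences(["ALKDYTREW", "GAKLMNPQR"], HlaClass.I,
                                      patient_id="P1")
        write_ligand_table(ls, tmp_path / "out.tsv", provenance="unit")
        back, _ = read_ligand_table(tmp_path / "out.tsv", HlaClass.I)
        assert back.sequences() == ls.sequences()


class TestValidation:
    @pytest.mark.parametrize("bad", ["", "ALX9K", "AL K", "alb1"])
    def test_invalid_sequences_rejected(self, bad):
        with pytest.raises(AlphabetError):
            validate_peptide(bad)

    def test_case_insensitive_at_ingest(self):
        assert validate_peptide("alkdy") == "ALKDY"

    @pytest.mark.parametrize("raw,expected", [
        ("A*02", "A*02"), ("a02", "A*02"), ("HLA-B*27", "B*27"), ("B7", "B*07")])
    def test_allele_normalization(self, raw, expected):
        assert normalize_allele(raw) == expected


class TestSubtract:
    def q(self, *seqs):
        return LigandSet.from_sequences(seqs, HlaClass.I)

    def test_exact_removal(self):
        out = subtract(self.q("ALKDYTREW", "GAKLMNPQR"), {"GAKLMNPQR"},
                       SubtractMode.EXACT)
        assert out.sequences() == ["ALKDYTREW"]

    def test_query_within_reference(self):
        out = subtract(self.q("SEQNVRAT"), {"KLSEQNVRATYW"},
                       SubtractMode.QUERY_WITHIN_REFERENCE)
        assert len(out) == 0

    def test_reference_within_query(self):
        query = LigandSet.from_sequences(["TLPLPNLRLVRGTQV"], HlaClass.II)
        out = subtract(query, {"PNLRLVRGT"}, SubtractMode.REFERENCE_WITHIN_QUERY)
        assert len(out) == 0

    def test_unknown_mode_raises(self):
        with pytest.raises(ValueError, match="mode"):
            subtract(self.q("ALKDYTREW"), set(), "fuzzy")

    def test_empty_reference_is_identity(self):
        q = self.q("ALKDYTREW", "GAKLMNPQR")
        for mode in SubtractMode:
            assert subtract(q, set(), mode).sequences() == q.sequences()

    def test_self_subtraction_exact_empties(self):
        q = self.q("ALKDYTREW", "GAKLMNPQR")
        assert len(subtract(q, q.sequence_set(), SubtractMode.EXACT)) == 0

    @settings(max_examples=60, deadline=None)
    @given(query=st.lists(peptides, max_size=30),
           ref=st.lists(peptides, max_size=30),
           mode=st.sampled_from(list(SubtractMode)))
    def test_agrees_with_bruteforce_oracle(self, query, ref, mode):
        """Each mode must match a quadratic all-pairs substring check."""
        qset = LigandSet.from_sequences(query, HlaClass.I)
        out = subtract(qset, ref, mode)
        refs = [r.upper() for r in ref]

        def removed(s):
            if mode is SubtractMode.EXACT:
                return any(s == r for r in refs)
            if mode is SubtractMode.QUERY_WITHIN_REFERENCE:
                return any(s in r for r in refs)
            return any(r in s for r in refs)

        expected = [s for s in qset.sequences() if not removed(s)]
        assert out.sequences() == expected
        assert len(out) <= len(qset)


class TestIsNested:
    @pytest.mark.parametrize("a,b,expected", [
        ("AAAA", "AAAA", True),
        ("NPPSM", "NPPSMVAAGSVVAAV", True),
        ("ALK", "GAK", False),
    ])
    def test_examples(self, a, b, expected):
        assert is_nested(a, b) is expected

    @settings(max_examples=60, deadline=None)
    @given(a=peptides, b=peptides)
    def test_symmetric_and_matches_enumeration(self, a, b):
        brute = any(b[i:i + len(a)] == a for i in range(len(b) - len(a) + 1)) \
            or any(a[i:i + len(b)] == b for i in range(len(a) - len(b) + 1))
        assert is_nested(a, b) == is_nested(b, a) == brute

    @given(a=peptides)
    @settings(max_examples=20, deadline=None)
    def test_reflexive(self, a):
        assert is_nested(a, a)
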