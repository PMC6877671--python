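"""Variant/fusion filtering, protein editing, window scanning and 15-mer design."""

import numpy as np
import pytest

from episelect.binding import AlleleScoreMatrix, MatrixRegistry, relative_score_raw
from episelect.core import AMINO_ACIDS, PatientHLA
from episelect.errors import EpiselectError, FormatError, UnextendableError
from episelect.neoantigen import (ChangeKind, FusionEvent, MutatedWindow,
                                  ProteinChange, SomaticVariant,
                                  apply_protein_change, extend_to_15mer,
                                  filter_fusions, filter_somatic_variants,
                                  mutated_positions_of, predict_long_peptides,
                                  read_fusion_table, read_variant_table,
                                  scan_mutated_windows)

from conftest import write_tsv

ERBB3_WT = "TLPLPNLRVVRGTQV"
ERBB3_MUT = "TLPLPNLRLVRGTQV"


def make_variant(**kwargs):
    defaults = dict(gene="G", transcript_ids=("T1",),
                    protein_change=ProteinChange(9, "V", "L"),
                    tumor_depth=30, normal_alt_reads=0)
    defaults.update(kwargs)
    return SomaticVariant(**defaults)


class TestVariantFilter:
    def test_passing_variant_kept(self):
        assert filter_somatic_variants([make_variant()]) == [make_variant()]

    @pytest.mark.parametrize("kwargs", [
        dict(tumor_depth=25),                 # strict >25
        dict(normal_alt_reads=1),             # detectable in normal
        dict(multi_locus=True),               # ambiguous transcript
        dict(consequence="synonymous"),
    ])
    def test_each_rule_rejects(self, kwargs):
        assert filter_somatic_variants([make_variant(**kwargs)]) == []

    def test_whitelist_restricts_genes(self):
        variants = [make_variant(gene="ERBB3"), make_variant(gene="OTHER")]
        kept = filter_somatic_variants(variants, gene_whitelist=["erbb3"])
        assert [v.gene for v in kept] == ["ERBB3"]


class TestFusionFilter:
    def test_boundaries_are_strict(self):
        kept = filter_fusions([
            FusionEvent("ME2", "SMAD4", split_reads=12, probability=0.9),
            FusionEvent("A", "B", split_reads=10, probability=0.9),
            FusionEvent("C", "D", split_reads=50, probability=0.5),
        ])
        assert [(f.gene_5p, f.gene_3p) for f in kept] == [("ME2", "SMAD4")]

    def test_probability_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            FusionEvent("A", "B", split_reads=20, probability=1.5)

    def test_whitelist_needs_one_partner(self):
        fusion = FusionEvent("ME2", "SMAD4", split_reads=20, probability=0.95)
        assert filter_fusions([fusion], gene_whitelist=["SMAD4"]) == [fusion]
        assert filter_fusions([fusion], gene_whitelist=["KRAS"]) == []


class TestApplyProteinChange:
    def test_substitution_reproduces_known_neoepitope_pair(self):
        assert apply_protein_change(
            ERBB3_WT, ProteinChange(9, "V", "L")) == ERBB3_MUT

    def test_identity_substitution_warns_and_returns_input(self):
        with pytest.warns(UserWarning):
            out = apply_protein_change(ERBB3_WT, ProteinChange(9, "V", "V"))
        assert out == ERBB3_WT

    def test_reference_mismatch_raises(self):
        with pytest.raises(EpiselectError, match="mismatch"):
            apply_protein_change(ERBB3_WT, ProteinChange(9, "A", "L"))

    def test_inframe_insertion_and_deletion(self):
        ins = ProteinChange(3, "P", "QQ", ChangeKind.INFRAME_INS)
        assert apply_protein_change("TLPLP", ins) == "TLPQQLP"
        dele = ProteinChange(2, "L", "", ChangeKind.INFRAME_DEL)
        assert apply_protein_change("TLPLP", dele) == "TPLP"

    def test_frameshift_replaces_suffix(self):
        fs = ProteinChange(4, "L", "WWWW", ChangeKind.FRAMESHIFT)
        assert apply_protein_change("TLPLP", fs) == "TLPWWWW"


class TestScanWindows:
    def test_hand_enumerated_example(self, toy_registry, toy_patient):
        """Protein AAAALKAAA, mutation at position 5 (L): the only length-3
        window over the mutation scoring >60% is ALK at 4-6."""
        windows = scan_mutated_windows("AAAALKAAA", [5], toy_patient,
                                       toy_registry, rel_threshold=60)
        assert [(w.sequence, w.span) for w in windows] == [("ALK", (4, 6))]
        assert windows[0].best_relative_score == 100.0
        assert windows[0].allele == "A*01"

    def test_terminus_windows_clipped_to_protein(self, toy_registry, toy_patient):
        windows = scan_mutated_windows("ALK", [1], toy_patient, toy_registry,
                                       rel_threshold=0)
        assert [(w.sequence, w.span) for w in windows] == [("ALK", (1, 3))]

    def test_unreachable_threshold_gives_empty_list(self, toy_registry,
                                                    toy_patient):
        assert scan_mutated_windows("AAAGAKAAA", [5], toy_patient,
                                    toy_registry, rel_threshold=100) == []

    def test_every_window_contains_a_mutated_position(self, toy_registry,
                                                      toy_patient):
        windows = scan_mutated_windows("AAAALKAAA", [5], toy_patient,
                                       toy_registry, rel_threshold=0)
        for w in windows:
            assert any(w.span[0] <= p <= w.span[1] for p in w.mutated_positions)

    def test_agrees_with_bruteforce_enumerator(self):
        """50 random (protein, matrix) instances against an independent
        enumerator of all mutation-spanning windows."""
        rng = np.random.default_rng(17)
        patient = PatientHLA("P1", ("A*01",))
        for trial in range(50):
            n = int(rng.integers(12, 60))
            protein = "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, n))
            length = int(rng.integers(8, 11))
            weights = {p + 1: {res: int(rng.integers(0, 10))
                               for res in AMINO_ACIDS}
                       for p in range(length)}
            matrix = AlleleScoreMatrix("A*01", length, weights)
            registry = MatrixRegistry([matrix])
            mut_pos = int(rng.integers(1, n + 1))
            threshold = float(rng.uniform(40, 80))
            got = scan_mutated_windows(protein, [mut_pos], patient, registry,
                                       threshold)
            expected = []
            for start in range(1, n - length + 2):
                end = start + length - 1
                if not start <= mut_pos <= end:
                    continue
                seq = protein[start - 1:end]
                rel = 100.0 * sum(weights[i + 1][r] for i, r in enumerate(seq)) \
                    / matrix.max_score
                if rel > threshold:
                    expected.append((seq, (start, end)))
            assert sorted((w.sequence, w.span) for w in got) == sorted(expected)
            for w in got:  # round-trip: sequence occurs at its recorded span
                assert protein[w.span[0] - 1:w.span[1]] == w.sequence


class TestExtendTo15mer:
    def window(self, seq, span, mut=None):
        return MutatedWindow(sequence=seq, protein="G", span=span,
                             mutated_positions=tuple(mut or (span[0],)),
                             best_relative_score=100.0, allele="A*01")

    def test_symmetric_flanks_for_centered_window(self):
        protein = "A" * 10 + "CDEFGHIKL" + "A" * 10  # window at 11-19
        lp = extend_to_15mer(self.window("CDEFGHIKL", (11, 19), (15,)), protein)
        assert lp.span == (8, 22) and len(lp.sequence) == 15
        assert "CDEFGHIKL" in lp.sequence

    def test_n_terminal_clipping_shifts_deficit_to_c_side(self):
        protein = "CDEFGHIKL" + "A" * 31
        lp = extend_to_15mer(self.window("CDEFGHIKL", (1, 9), (2,)), protein)
        assert lp.span == (1, 15)

    def test_c_terminal_clipping_shifts_deficit_to_n_side(self):
        protein = "A" * 31 + "CDEFGHIKL"
        lp = extend_to_15mer(self.window("CDEFGHIKL", (32, 40), (35,)), protein)
        assert lp.span == (26, 40)

    def test_odd_remainder_goes_c_terminal(self):
        protein = "A" * 40
        lp = extend_to_15mer(self.window("A" * 8, (10, 17), (12,)), protein)
        # flank 7 -> 3 left, 4 right
        assert lp.span == (7, 21)

    def test_known_neoepitope_15mer_with_wildtype_counterpart(self):
        lp = extend_to_15mer(self.window("LRLVRGTQV", (7, 15), (9,)),
                             ERBB3_MUT, ERBB3_WT)
        assert lp.sequence == ERBB3_MUT
        assert lp.wildtype_counterpart == ERBB3_WT
        diffs = [i for i, (a, b) in enumerate(
            zip(lp.sequence, lp.wildtype_counterpart)) if a != b]
        assert len(diffs) == 1  # wildtype differs only at the edit

    def test_short_protein_unextendable(self):
        with pytest.raises(UnextendableError):
            extend_to_15mer(self.window("CDEFGHIKL", (1, 9)), "CDEFGHIKLAAA")

    def test_output_contains_window_and_mutation(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            n = int(rng.integers(15, 50))
            protein = "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, n))
            length = int(rng.integers(8, 13))
            start = int(rng.integers(1, n - length + 2))
            mut = int(rng.integers(start, start + length))
            w = self.window(protein[start - 1:start + length - 1],
                            (start, start + length - 1), (mut,))
            lp = extend_to_15mer(w, protein)
            assert len(lp.sequence) == 15
            assert w.sequence in lp.sequence
            assert len(lp.mutated_positions) >= 1


class TestEndToEnd:
    def test_variant_to_long_peptide(self, toy_registry):
        """A substitution creating the toy matrix's optimal 3-mer yields a
        15-mer covering it with a one-residue wildtype difference."""
        patient = PatientHLA("P1", ("A*01",))
        wt = "CDEFGADKCDEFGHCDEFG"
        variant = make_variant(gene="G", protein_change=ProteinChange(7, "D", "L"))
        # mutated: CDEFGALKCDEFGHCDEFG ; window ALK at 6-8 scores 100%
        peptides = predict_long_peptides(variant, wt, patient, toy_registry,
                                         rel_threshold=60)
        assert len(peptides) >= 1
        lp = peptides[0]
        assert len(lp.sequence) == 15
        assert sum(a != b for a, b in
                   zip(lp.sequence, lp.wildtype_counterpart)) == 1


class TestTableReaders:
    def test_variant_table(self, tmp_path):
        path = write_tsv(
            tmp_path / "v.tsv",
            ["gene", "transcript", "protein_change", "tumor_depth",
             "normal_alt_reads", "consequence", "multi_locus"],
            [["ERBB3", "ENST1", "V104L", 40, 0, "missense", 0]])
        variants = read_variant_table(path)
        assert variants[0].protein_change == ProteinChange(104, "V", "L")

    def test_variant_table_missing_depth_column(self, tmp_path):
        path = write_tsv(tmp_path / "v.tsv",
                         ["gene", "transcript", "protein_change",
                          "normal_alt_reads"],
                         [["G", "T", "V1L", 0]])
        with pytest.raises(FormatError, match="tumor_depth"):
            read_variant_table(path)

    def test_fusion_table(self, tmp_path):
        path = write_tsv(tmp_path / "f.tsv",
                         ["gene_5p", "gene_3p", "split_reads", "probability"],
                         [["ME2", "SMAD4", 15, 0.95]])
        fusions = read_fusion_table(path)
        assert fusions[0].split_reads == 15
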