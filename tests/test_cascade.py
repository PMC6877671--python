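"""Class I / class II selection cascades: planted-truth recovery, step
semantics, order-invariance of exact subtraction."""

import itertools

import numpy as np
import pytest

from episelect.binding import MatrixRegistry
from episelect.cascade import (CLASS_I_STEP_ORDER, CascadeConfig,
                               ReferenceCompendium, run_classI_cascade,
                               run_classII_cascade)
from episelect.core import AMINO_ACIDS, HlaClass, LigandSet
from episelect.errors import ConfigurationError
from episelect.synth import LigandomeSpec, gen_ligandome_scenario


def empty_refs():
    e_i = lambda: LigandSet(HlaClass.I)
    e_ii = lambda: LigandSet(HlaClass.II)
    return ReferenceCompendium(
        autologous_nml_i=e_i(), cohort_nml_i=e_i(), nmt_colon_i=e_i(),
        benign_multi_tissue_i=e_i(), autologous_nml_ii=e_ii(),
        cohort_nml_ii=e_ii(), nmt_colon_ii=e_ii(),
        benign_multi_tissue_ii=e_ii(), classII_ligands_for_nesting=e_ii())


@pytest.fixture(scope="module")
def scenario():
    return gen_ligandome_scenario(
        LigandomeSpec(seed=11, n_nested_pairs=5, n_classI_containing_ii=4))


class TestClassICascade:
    def test_planted_truth_recovered_exactly(self, scenario):
        res = run_classI_cascade(scenario.tumor_classI, scenario.patient,
                                 scenario.refs, scenario.matrices)
        assert set(res.final_candidates.sequences()) == set(scenario.planted_classI)

    def test_counts_are_monotone_nonincreasing(self, scenario):
        res = run_classI_cascade(scenario.tumor_classI, scenario.patient,
                                 scenario.refs, scenario.matrices)
        counts = [n for _, n in res.counts()]
        assert counts == sorted(counts, reverse=True)
        assert len(res.final_candidates) == counts[-1]

    def test_retained_sets_are_nested(self, scenario):
        res = run_classI_cascade(scenario.tumor_classI, scenario.patient,
                                 scenario.refs, scenario.matrices)
        previous = scenario.tumor_classI.sequence_set()
        for _, _, retained in res.step_trace:
            current = retained.sequence_set()
            assert current <= previous
            previous = current

    def test_empty_tumor_gives_all_zero_counts(self, scenario):
        res = run_classI_cascade(LigandSet(HlaClass.I), scenario.patient,
                                 scenario.refs, scenario.matrices)
        assert all(n == 0 for _, n in res.counts())
        assert len(res.final_candidates) == 0

    def test_nesting_step_removes_exactly_the_planted_pairs(self, scenario):
        res = run_classI_cascade(scenario.tumor_classI, scenario.patient,
                                 scenario.refs, scenario.matrices)
        counts = dict(res.counts())
        removed = counts["subtract_benign_multi"] - counts["remove_classII_nested"]
        assert removed == len(scenario.nested_pair_peptides) == 5

    def test_missing_reference_names_the_subset(self, scenario):
        refs = empty_refs()
        refs.nmt_colon_i = None
        with pytest.raises(ConfigurationError, match="nmt_colon_i"):
            run_classI_cascade(scenario.tumor_classI, scenario.patient, refs,
                               scenario.matrices)

    def test_disabling_a_step_never_shrinks_the_final_set(self, scenario):
        base = run_classI_cascade(scenario.tumor_classI, scenario.patient,
                                  scenario.refs, scenario.matrices)
        for step in CLASS_I_STEP_ORDER:
            res = run_classI_cascade(
                scenario.tumor_classI, scenario.patient, scenario.refs,
                scenario.matrices,
                config=CascadeConfig(disabled_steps=(step,)))
            assert base.final_candidates.sequence_set() <= \
                res.final_candidates.sequence_set()

    def test_exact_subtraction_order_does_not_change_membership(self, scenario):
        subtraction = ("subtract_nml", "subtract_nmt", "subtract_benign_multi")
        head = ("binders", "motif")
        tail = ("remove_classII_nested", "strong_binders")
        finals = set()
        for perm in itertools.permutations(subtraction):
            cfg = CascadeConfig(step_order=head + perm + tail)
            res = run_classI_cascade(scenario.tumor_classI, scenario.patient,
                                     scenario.refs, scenario.matrices, config=cfg)
            finals.add(res.final_candidates.sequence_set())
        assert len(finals) == 1

    def test_empty_references_reduce_to_strong_binder_filter(self, scenario):
        """With empty references the cascade is the >60% relative-score
        filter; cross-check against a one-pass brute force on 500 random
        peptides."""
        rng = np.random.default_rng(5)
        seqs = {"".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=9))
                for _ in range(500)}
        tumor = LigandSet.from_sequences(sorted(seqs), HlaClass.I)
        res = run_classI_cascade(tumor, scenario.patient, empty_refs(),
                                 scenario.matrices)
        from episelect.binding import relative_score_raw
        expected = set()
        for seq in tumor:
            best = max(relative_score_raw(seq, scenario.matrices.get(a, 9))
                       for a in scenario.patient.class_i_alleles)
            if best > 60:
                expected.add(seq)
        assert res.final_candidates.sequence_set() == expected

    def test_final_candidates_sorted_by_score_then_lexicographic(self, scenario):
        res = run_classI_cascade(scenario.tumor_classI, scenario.patient,
                                 scenario.refs, scenario.matrices)
        from episelect.binding import relative_score_raw
        seqs = res.final_candidates.sequences()
        keys = []
        for s in seqs:
            best = max(relative_score_raw(s, scenario.matrices.get(a, 9))
                       for a in scenario.patient.class_i_alleles)
            keys.append((-best, s))
        assert keys == sorted(keys)


class TestClassIICascade:
    def test_planted_truth_recovered_exactly(self, scenario):
        res = run_classII_cascade(scenario.tumor_classII, scenario.refs)
        assert set(res.final_candidates.sequences()) == set(scenario.planted_classII)

    def test_containment_step_removes_candidates_with_benign_core(self, scenario):
        res = run_classII_cascade(scenario.tumor_classII, scenario.refs)
        counts = dict(res.counts())
        removed = counts["subtract_benign_multi"] - counts["remove_containing_classI"]
        assert removed == len(scenario.classI_containing_ii) == 4

    def test_candidate_with_embedded_benign_classI_ligand_removed(self):
        refs = empty_refs()
        refs.cohort_nml_i = LigandSet.from_sequences(["SMVAAGSVV"], HlaClass.I)
        tumor = LigandSet.from_sequences(["NPPSMVAAGSVVAAV"], HlaClass.II)
        res = run_classII_cascade(tumor, refs)
        assert len(res.final_candidates) == 0
        assert dict(res.counts())["remove_containing_classI"] == 0

    def test_tumor_identical_to_autologous_nml_yields_empty(self):
        seqs = ["NPPSMVAAGSVVAAV", "TLPLPNLRLVRGTQV"]
        refs = empty_refs()
        refs.autologous_nml_ii = LigandSet.from_sequences(seqs, HlaClass.II)
        res = run_classII_cascade(
            LigandSet.from_sequences(seqs, HlaClass.II), refs)
        assert len(res.final_candidates) == 0

    def test_autologous_step_skippable_when_nml_missing(self):
        refs = empty_refs()
        refs.autologous_nml_ii = None
        tumor = LigandSet.from_sequences(["NPPSMVAAGSVVAAV"], HlaClass.II)
        cfg = CascadeConfig(disabled_steps=("subtract_autologous_nml",))
        res = run_classII_cascade(tumor, refs, cfg)
        assert res.final_candidates.sequences() == ["NPPSMVAAGSVVAAV"]

    def test_length_variant_flag_removes_nested_at_t1(self):
        refs = empty_refs()
        refs.autologous_nml_ii = LigandSet.from_sequences(
            ["NPPSMVAAGSVVAAVAAQQ"], HlaClass.II)
        tumor = LigandSet.from_sequences(["NPPSMVAAGSVVAAV"], HlaClass.II)
        exact = run_classII_cascade(tumor, refs)
        assert len(exact.final_candidates) == 1
        nested = run_classII_cascade(
            tumor, refs, CascadeConfig(classII_length_variants_at_t1=True))
        assert len(nested.final_candidates) == 0

    def test_wrong_class_rejected(self, scenario):
        with pytest.raises(ConfigurationError):
            run_classII_cascade(scenario.tumor_classI, scenario.refs)
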