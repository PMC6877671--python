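"""Tumor-exclusive HLA ligand selection cascades.

Starting from all peptides eluted from a patient's tumor, a series of
filters narrows the pool down to tumor-exclusive, well-binding candidates:

HLA class I (seven steps, in the default order):

1. binder classification against the patient's alleles (matrix and/or
   affinity predictor, relative score > 50% of the maximal allelic score or
   IC50 < 500 nM);
2. motif confirmation (default: matrix relative score > 50% on at least one
   patient allele; a stricter predictor-agreement mode is selectable);
3. subtraction of autologous and cohort non-malignant liver (NML) ligands;
4. subtraction of non-malignant colon tissue (NMT) ligands;
5. subtraction of a benign multi-tissue class I compendium;
6. removal of peptides nested inside any class II ligand (shorter length
   variants of class II peptides co-purify in class I eluates);
7. retention of peptides with relative score > 60% on >= 1 patient allele.

HLA class II (five steps): exact subtraction of autologous NML (optionally
with length-variant removal), cohort NML, NMT and a benign multi-tissue
class II compendium, then removal of candidates that contain any benign
class I ligand as a contiguous substring.

Each step is a named, individually disableable filter; the result carries a
per-step retained-count trace. For exact-subtraction steps the final
membership is order-independent (set difference commutes); only the
intermediate counts depend on the order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

from .binding import AffinityPredictor, MatrixRegistry, classify_binder, relative_score_raw
from .core import HlaClass, LigandSet, PatientHLA, SubtractMode, subtract
from .errors import ConfigurationError

CLASS_I_STEP_ORDER = (
    "binders", "motif", "subtract_nml", "subtract_nmt",
    "subtract_benign_multi", "remove_classII_nested", "strong_binders",
)

CLASS_II_STEP_ORDER = (
    "subtract_autologous_nml", "subtract_cohort_nml", "subtract_nmt",
    "subtract_benign_multi", "remove_containing_classI",
)


@dataclass
class ReferenceCompendium:
    """The benign reference ligandomes a cascade subtracts against.

    Class I and class II roles are kept separate because the two cascades
    consume different compendia (and the cross-class steps need the opposite
    class). A role left as None is *missing*: running a step that needs it
    raises a configuration error, unless the step is disabled. Use an empty
    LigandSet for a present-but-empty reference.
    """

    autologous_nml_i: Optional[LigandSet] = None
    cohort_nml_i: Optional[LigandSet] = None
    nmt_colon_i: Optional[LigandSet] = None
    benign_multi_tissue_i: Optional[LigandSet] = None  # 132-tissue-style database
    autologous_nml_ii: Optional[LigandSet] = None
    cohort_nml_ii: Optional[LigandSet] = None
    nmt_colon_ii: Optional[LigandSet] = None
    benign_multi_tissue_ii: Optional[LigandSet] = None  # 82-tissue-style database
    classII_ligands_for_nesting: Optional[LigandSet] = None

    def require(self, role: str) -> LigandSet:
        value = getattr(self, role)
        if value is None:
            raise ConfigurationError(
                f"reference compendium sub-set {role!r} is missing; "
                f"provide it or disable the step that uses it"
            )
        return value


@dataclass
class CascadeConfig:
    """Thresholds and switches for a cascade run."""

    syfpeithi_threshold: float = 50.0
    final_threshold: float = 60.0
    ic50_threshold: float = 500.0
    binder_rule: str = "or"            # "or" | "and" within an allele
    motif_mode: str = "matrix"         # "matrix" | "both" (predictor agreement)
    classII_length_variants_at_t1: bool = False
    disabled_steps: tuple[str, ...] = ()
    step_order: tuple[str, ...] | None = None  # None = class default


@dataclass
class CascadeResult:
    """Ordered step trace plus the surviving candidate set."""

    patient_id: str
    hla_class: HlaClass
    step_trace: list[tuple[str, int, LigandSet]] = field(default_factory=list)
    final_candidates: LigandSet | None = None
    metadata: dict = field(default_factory=dict)

    def counts(self) -> list[tuple[str, int]]:
        return [(name, n) for name, n, _ in self.step_trace]


def _sorted_final(candidates: LigandSet, best_scores: dict[str, float]) -> LigandSet:
    """Deterministic report order: best relative score desc, then lexicographic."""
    order = sorted(candidates.sequences(),
                   key=lambda s: (-best_scores.get(s, 0.0), s))
    out = LigandSet(candidates.hla_class)
    for seq in order:
        rec = candidates.get(seq)
        out.add(rec)
        out.multiplicity[seq] = candidates.multiplicity[seq]
    return out


def run_classI_cascade(tumor: LigandSet, patient: PatientHLA,
                       refs: ReferenceCompendium, matrices: MatrixRegistry,
                       predictor: AffinityPredictor | None = None,
                       config: CascadeConfig | None = None) -> CascadeResult:
    """Run the seven-step class I selection cascade.

    Every enabled step logs the retained count; disabling a step (via
    ``config.disabled_steps``) skips it entirely, which can only enlarge the
    final set.
    """
    if tumor.hla_class is not HlaClass.I:
        raise ConfigurationError("class I cascade requires a class I tumor set")
    cfg = config or CascadeConfig()
    if len(tumor) and not matrices.lengths_for(patient.class_i_alleles) \
            and predictor is None:
        raise ConfigurationError(
            f"no score matrix for any allele of patient {patient.patient_id} "
            f"and no predictor supplied"
        )

    best_scores: dict[str, float] = {}

    def best_matrix_relative(seq: str) -> float | None:
        best: float | None = None
        for allele in patient.class_i_alleles:
            matrix = matrices.get(allele, len(seq))
            if matrix is not None:
                rel = relative_score_raw(seq, matrix)
                best = rel if best is None else max(best, rel)
        if best is not None:
            best_scores[seq] = best
        return best

    def step_binders(current: LigandSet) -> LigandSet:
        keep = []
        for seq in current:
            call = classify_binder(seq, patient, matrices, predictor,
                                   syfpeithi_threshold=cfg.syfpeithi_threshold,
                                   ic50_threshold=cfg.ic50_threshold,
                                   rule=cfg.binder_rule)
            best_matrix_relative(seq)
            if call.overall:
                keep.append(seq)
        return current.restricted_to(keep)

    def step_motif(current: LigandSet) -> LigandSet:
        keep = []
        for seq in current:
            rel = best_matrix_relative(seq)
            matrix_ok = rel is not None and rel > cfg.syfpeithi_threshold
            if cfg.motif_mode == "both" and predictor is not None:
                ic50s = [predictor(seq, a) for a in patient.class_i_alleles]
                ic50_ok = any(v is not None and v < cfg.ic50_threshold for v in ic50s)
                if matrix_ok and ic50_ok:
                    keep.append(seq)
            elif matrix_ok:
                keep.append(seq)
        return current.restricted_to(keep)

    def step_strong(current: LigandSet) -> LigandSet:
        keep = []
        for seq in current:
            rel = best_matrix_relative(seq)
            if rel is not None and rel > cfg.final_threshold:
                keep.append(seq)
        return current.restricted_to(keep)

    steps: dict[str, Callable[[LigandSet], LigandSet]] = {
        "binders": step_binders,
        "motif": step_motif,
        "subtract_nml": lambda cur: subtract(
            subtract(cur, refs.require("autologous_nml_i"), SubtractMode.EXACT),
            refs.require("cohort_nml_i"), SubtractMode.EXACT),
        "subtract_nmt": lambda cur: subtract(
            cur, refs.require("nmt_colon_i"), SubtractMode.EXACT),
        "subtract_benign_multi": lambda cur: subtract(
            cur, refs.require("benign_multi_tissue_i"), SubtractMode.EXACT),
        "remove_classII_nested": lambda cur: subtract(
            cur, refs.require("classII_ligands_for_nesting"),
            SubtractMode.QUERY_WITHIN_REFERENCE),
        "strong_binders": step_strong,
    }

    order = cfg.step_order or CLASS_I_STEP_ORDER
    return _run(order, steps, tumor, patient.patient_id, HlaClass.I, cfg,
                best_scores)


def run_classII_cascade(tumor: LigandSet, refs: ReferenceCompendium,
                        config: CascadeConfig | None = None,
                        patient_id: str = "") -> CascadeResult:
    """Run the five-step class II selection cascade.

    With ``config.classII_length_variants_at_t1`` set, the autologous-NML
    step removes nested length variants in either direction, not only exact
    matches.
    """
    if tumor.hla_class is not HlaClass.II:
        raise ConfigurationError("class II cascade requires a class II tumor set")
    cfg = config or CascadeConfig()

    def step_t1(current: LigandSet) -> LigandSet:
        nml = refs.require("autologous_nml_ii")
        out = subtract(current, nml, SubtractMode.EXACT)
        if cfg.classII_length_variants_at_t1:
            out = subtract(out, nml, SubtractMode.QUERY_WITHIN_REFERENCE)
            out = subtract(out, nml, SubtractMode.REFERENCE_WITHIN_QUERY)
        return out

    def step_t5(current: LigandSet) -> LigandSet:
        benign_i = refs.require("benign_multi_tissue_i")
        cohort_i = refs.require("cohort_nml_i")
        out = subtract(current, benign_i, SubtractMode.REFERENCE_WITHIN_QUERY)
        return subtract(out, cohort_i, SubtractMode.REFERENCE_WITHIN_QUERY)

    steps: dict[str, Callable[[LigandSet], LigandSet]] = {
        "subtract_autologous_nml": step_t1,
        "subtract_cohort_nml": lambda cur: subtract(
            cur, refs.require("cohort_nml_ii"), SubtractMode.EXACT),
        "subtract_nmt": lambda cur: subtract(
            cur, refs.require("nmt_colon_ii"), SubtractMode.EXACT),
        "subtract_benign_multi": lambda cur: subtract(
            cur, refs.require("benign_multi_tissue_ii"), SubtractMode.EXACT),
        "remove_containing_classI": step_t5,
    }

    order = cfg.step_order or CLASS_II_STEP_ORDER
    return _run(order, steps, tumor, patient_id, HlaClass.II, cfg, {})


def _run(order, steps, tumor, patient_id, hla_class, cfg, best_scores
         ) -> CascadeResult:
    unknown = set(order) - set(steps)
    if unknown:
        raise ConfigurationError(f"unknown cascade step(s): {sorted(unknown)}")
    result = CascadeResult(patient_id=patient_id, hla_class=hla_class,
                           metadata={"motif_mode": cfg.motif_mode,
                                     "binder_rule": cfg.binder_rule,
                                     "disabled_steps": list(cfg.disabled_steps)})
    current = tumor
    for name in order:
        if name in cfg.disabled_steps:
            continue
        current = steps[name](current)
        result.step_trace.append((name, len(current), current))
    result.final_candidates = _sorted_final(current, best_scores)
    return result


def cross_patient_candidates(peptide_sets: dict[str, LigandSet],
                             patient: PatientHLA, matrices: MatrixRegistry,
                             threshold: float = 60.0) -> dict[str, list[str]]:
    """Query helper: peptides found in *other* patients that bind this
    patient's alleles above ``threshold`` (relative score).

    Used when a patient's own tumor ligandome is unavailable and candidates
    must be borrowed from HLA-matched cohort members. The choice among the
    returned candidates remains a manual curation step.
    """
    out: dict[str, list[str]] = {}
    for other_id, ligands in peptide_sets.items():
        if other_id == patient.patient_id:
            continue
        hits = []
        for seq in ligands:
            for allele in patient.class_i_alleles:
                matrix = matrices.get(allele, len(seq))
                if matrix is not None and relative_score_raw(seq, matrix) > threshold:
                    hits.append(seq)
                    break
        if hits:
            out[other_id] = sorted(hits)
    return out
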