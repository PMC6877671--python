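"""Seeded synthetic-data generators with planted ground truth.

Every input the pipeline consumes can be generated here: tumor ligandomes
with a planted tumor-exclusive, strong-binding subset; benign reference
compendia (autologous and cohort non-malignant liver, non-malignant colon,
and multi-tissue class I / class II databases); anchored score matrices;
somatic variant tables with depth structure; ICS panels with planted
induced/enhanced/pre-existing responses; and IHC count tables with a group
effect. Each generator returns the truth it planted so that every pipeline
stage can be asserted against construction rather than against itself.

Determinism: one pseudo-random stream per generator, derived from the
scenario seed by stable sub-seeding (``numpy.random.SeedSequence`` with a
fixed spawn key per generator), so adding a generator never perturbs the
streams of the others and identical (seed, spec) pairs are bit-reproducible.

Default sizes mirror the study conditions the pipeline targets: tumor
ligandomes of several hundred class I peptides of which a small planted
subset is tumor-exclusive and strongly binding, cohorts of a handful of
patients, ICS subsets of tens of thousands of gated events with background
marker frequencies of 0.05-0.15%, and IHC groups of 8 and 7 patients with
five high-power fields each.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .binding import AlleleScoreMatrix, MatrixRegistry
from .cascade import ReferenceCompendium
from .core import AMINO_ACIDS, HlaClass, LigandRecord, LigandSet, PatientHLA, Tissue
from .errors import GenerationError
from .ics import MARKERS
from .ihc import Compartment, PatientGroup

_STREAMS = {"matrix": 11, "ligandome": 23, "variants": 37, "ics": 53, "ihc": 71}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(_STREAMS[stream],)))


# ---------------------------------------------------------------------------
# Score matrices
# ---------------------------------------------------------------------------

def gen_score_matrix(seed: int, length: int = 9,
                     anchor_positions: Sequence[int] = (2, 9),
                     allele: str = "A*01", anchor_weight: int = 12,
                     background_weight: int = 1) -> AlleleScoreMatrix:
    """An anchored PSSM: at each anchor position one dominant residue carries
    ``anchor_weight`` and all others 0; every non-anchor position gives all
    20 residues ``background_weight``. Without anchors the matrix is uniform
    and every peptide scores 100% of the maximal allelic score.
    """
    if length < 8:
        raise GenerationError(f"class I matrix length must be >= 8, got {length}")
    anchors = sorted(set(int(p) for p in anchor_positions))
    if any(p < 1 or p > length for p in anchors):
        raise GenerationError("anchor position outside matrix length")
    rng = _rng(seed, "matrix")
    weights: dict[int, dict[str, int]] = {}
    for pos in range(1, length + 1):
        if pos in anchors:
            residue = AMINO_ACIDS[rng.integers(len(AMINO_ACIDS))]
            col = {res: 0 for res in AMINO_ACIDS}
            col[residue] = anchor_weight
        else:
            col = {res: background_weight for res in AMINO_ACIDS}
        weights[pos] = col
    return AlleleScoreMatrix(allele=allele, length=length, weights=weights)


def anchor_residues(matrix: AlleleScoreMatrix) -> dict[int, str]:
    """Positions whose single top residue dominates (weight > 2x the runner-up)."""
    out = {}
    for pos in range(1, matrix.length + 1):
        col = sorted(matrix.weights[pos].items(), key=lambda kv: -kv[1])
        if len(col) > 1 and col[0][1] > 2 * max(col[1][1], 1):
            out[pos] = col[0][0]
    return out


# ---------------------------------------------------------------------------
# Ligandome scenario
# ---------------------------------------------------------------------------

@dataclass
class LigandomeSpec:
    """Sizes and composition of a synthetic ligandome scenario."""

    seed: int = 0
    patient_id: str = "SYN01"
    alleles: tuple[str, ...] = ("A*01", "B*07")
    peptide_length_i: int = 9
    peptide_length_ii: int = 15
    n_planted_exclusive_i: int = 20      # tumor-exclusive strong binders (truth)
    n_weak_exclusive_i: int = 180        # tumor-exclusive non-binders
    n_shared_i: int = 300                # present in tumor and references
    n_nested_pairs: int = 0              # strong binders removed at the nesting step
    n_reference_background_i: int = 150  # reference-only peptides
    n_planted_exclusive_ii: int = 15
    n_shared_ii: int = 120
    n_classI_containing_ii: int = 0      # class II peptides removed at the
    n_reference_background_ii: int = 80  # cross-class containment step


@dataclass
class LigandomeScenario:
    """A generated scenario: inputs plus planted truth."""

    spec: LigandomeSpec
    patient: PatientHLA
    matrices: MatrixRegistry
    tumor_classI: LigandSet
    tumor_classII: LigandSet
    refs: ReferenceCompendium
    planted_classI: list[str]
    planted_classII: list[str]
    nested_pair_peptides: list[str]       # class I peptides planted for nesting removal
    classI_containing_ii: list[str]       # class II peptides planted for containment removal


def _random_peptide(rng: np.random.Generator, length: int) -> str:
    idx = rng.integers(0, len(AMINO_ACIDS), size=length)
    return "".join(AMINO_ACIDS[i] for i in idx)


def _unique_peptide(rng, length, used: set[str], forbid_substring_of=(),
                    transform=None, max_tries: int = 1000) -> str:
    for _ in range(max_tries):
        pep = _random_peptide(rng, length)
        if transform:
            pep = transform(pep)
        if pep in used:
            continue
        if any(pep in longer for longer in forbid_substring_of):
            continue
        used.add(pep)
        return pep
    raise GenerationError(
        "could not generate a unique peptide; alphabet or length too constrained")


def gen_ligandome_scenario(spec: LigandomeSpec) -> LigandomeScenario:
    """Generate tumor ligandomes, reference compendia and planted truth.

    Construction guarantees: planted class I peptides match all anchor
    residues of one patient allele (relative score 100%), are absent from
    every reference set, and are not nested in any class II ligand; weak
    exclusives avoid every allele's anchor residues (relative score well
    below 50%); shared peptides are placed in both the tumor and at least
    one reference subtraction set. The class II scenario mirrors this
    without binding: planted exclusives versus shared peptides, plus
    optional peptides that contain a benign class I ligand as a substring.
    """
    rng = _rng(spec.seed, "ligandome")
    matrices = MatrixRegistry()
    for i, allele in enumerate(spec.alleles):
        matrices.add(gen_score_matrix(
            seed=spec.seed * 101 + i, length=spec.peptide_length_i,
            anchor_positions=(2, spec.peptide_length_i), allele=allele))
    patient = PatientHLA(spec.patient_id, tuple(spec.alleles))
    anchor_maps = {a: anchor_residues(matrices.get(a, spec.peptide_length_i))
                   for a in patient.class_i_alleles}
    all_anchor_residues = {pos: {m[pos] for m in anchor_maps.values() if pos in m}
                           for pos in range(1, spec.peptide_length_i + 1)}

    used: set[str] = set()

    def match_allele(pep: str, allele: str) -> str:
        chars = list(pep)
        for pos, res in anchor_maps[allele].items():
            chars[pos - 1] = res
        return "".join(chars)

    def avoid_all_anchors(pep: str) -> str:
        chars = list(pep)
        for pos, residues in all_anchor_residues.items():
            if not residues:
                continue
            while chars[pos - 1] in residues:
                chars[pos - 1] = AMINO_ACIDS[rng.integers(len(AMINO_ACIDS))]
        return "".join(chars)

    alleles_cycle = list(patient.class_i_alleles)
    planted_i = [
        _unique_peptide(rng, spec.peptide_length_i, used,
                        transform=lambda p, a=alleles_cycle[k % len(alleles_cycle)]:
                        match_allele(p, a))
        for k in range(spec.n_planted_exclusive_i)]
    weak_i = [_unique_peptide(rng, spec.peptide_length_i, used,
                              transform=avoid_all_anchors)
              for _ in range(spec.n_weak_exclusive_i)]
    shared_i = [_unique_peptide(rng, spec.peptide_length_i, used)
                for _ in range(spec.n_shared_i)]
    ref_only_i = [_unique_peptide(rng, spec.peptide_length_i, used)
                  for _ in range(spec.n_reference_background_i)]

    # nesting pairs: strong-binder class I peptides embedded inside class II
    # ligands of the nesting reference; they survive every subtraction step
    # and are removed exactly at the class II nesting step.
    nested_i: list[str] = []
    nesting_ii: list[str] = []
    for k in range(spec.n_nested_pairs):
        allele = alleles_cycle[k % len(alleles_cycle)]
        pep = _unique_peptide(rng, spec.peptide_length_i, used,
                              transform=lambda p, a=allele: match_allele(p, a))
        flank = spec.peptide_length_ii - spec.peptide_length_i
        left = flank // 2
        host = (_random_peptide(rng, left) + pep
                + _random_peptide(rng, flank - left))
        if host in used:
            host = _random_peptide(rng, left) + pep + _random_peptide(rng, flank - left)
        used.add(host)
        nested_i.append(pep)
        nesting_ii.append(host)

    def build_set(seqs, hla_class, tissue, patient_id=""):
        ls = LigandSet(hla_class)
        for s in seqs:
            ls.add(LigandRecord(peptide=s, patient_id=patient_id,
                                tissue=tissue, hla_class=hla_class))
        return ls

    tumor_i = build_set(planted_i + weak_i + shared_i + nested_i, HlaClass.I,
                        Tissue.TUMOR, spec.patient_id)

    # distribute shared peptides round-robin over the four class I
    # subtraction roles so every step removes something
    roles_i: dict[str, list[str]] = {"auto": [], "cohort": [], "nmt": [], "multi": []}
    role_names = list(roles_i)
    for k, s in enumerate(shared_i):
        roles_i[role_names[k % 4]].append(s)
    bg_split = max(1, len(ref_only_i) // 4)
    for k, name in enumerate(role_names):
        roles_i[name].extend(ref_only_i[k * bg_split:(k + 1) * bg_split])

    # --- class II ---
    long_refs = nesting_ii[:]  # forbid planted class II exclusives nesting there
    planted_ii = [_unique_peptide(rng, spec.peptide_length_ii, used)
                  for _ in range(spec.n_planted_exclusive_ii)]
    shared_ii = [_unique_peptide(rng, spec.peptide_length_ii, used)
                 for _ in range(spec.n_shared_ii)]
    ref_only_ii = [_unique_peptide(rng, spec.peptide_length_ii, used)
                   for _ in range(spec.n_reference_background_ii)]
    containing_ii: list[str] = []
    benign_i_for_containment: list[str] = []
    for _ in range(spec.n_classI_containing_ii):
        inner = _unique_peptide(rng, spec.peptide_length_i, used,
                                transform=avoid_all_anchors)
        flank = spec.peptide_length_ii - spec.peptide_length_i
        left = flank // 2
        host = _random_peptide(rng, left) + inner + _random_peptide(rng, flank - left)
        used.add(host)
        containing_ii.append(host)
        benign_i_for_containment.append(inner)

    tumor_ii = build_set(planted_ii + shared_ii + containing_ii, HlaClass.II,
                         Tissue.TUMOR, spec.patient_id)
    roles_ii: dict[str, list[str]] = {"auto": [], "cohort": [], "nmt": [], "multi": []}
    for k, s in enumerate(shared_ii):
        roles_ii[role_names[k % 4]].append(s)
    bg2 = max(1, len(ref_only_ii) // 4)
    for k, name in enumerate(role_names):
        roles_ii[name].extend(ref_only_ii[k * bg2:(k + 1) * bg2])

    refs = ReferenceCompendium(
        autologous_nml_i=build_set(roles_i["auto"], HlaClass.I, Tissue.NML,
                                   spec.patient_id),
        cohort_nml_i=build_set(roles_i["cohort"] + benign_i_for_containment,
                               HlaClass.I, Tissue.NML),
        nmt_colon_i=build_set(roles_i["nmt"], HlaClass.I, Tissue.NMT),
        benign_multi_tissue_i=build_set(roles_i["multi"], HlaClass.I,
                                        Tissue.BENIGN_OTHER),
        autologous_nml_ii=build_set(roles_ii["auto"], HlaClass.II, Tissue.NML,
                                    spec.patient_id),
        cohort_nml_ii=build_set(roles_ii["cohort"], HlaClass.II, Tissue.NML),
        nmt_colon_ii=build_set(roles_ii["nmt"], HlaClass.II, Tissue.NMT),
        benign_multi_tissue_ii=build_set(roles_ii["multi"], HlaClass.II,
                                         Tissue.BENIGN_OTHER),
        classII_ligands_for_nesting=build_set(nesting_ii + ref_only_ii[:20],
                                              HlaClass.II, Tissue.NML),
    )

    # construction checks: planted truth collides with nothing that would
    # remove it
    all_ref_i = (set(roles_i["auto"]) | set(roles_i["cohort"])
                 | set(roles_i["nmt"]) | set(roles_i["multi"]))
    if set(planted_i) & all_ref_i:
        raise GenerationError("planted class I peptide collides with a reference set")
    for pep in planted_i:
        if any(pep in host for host in refs.classII_ligands_for_nesting):
            raise GenerationError("planted class I peptide nested in a class II ligand")
    all_ref_ii = (set(roles_ii["auto"]) | set(roles_ii["cohort"])
                  | set(roles_ii["nmt"]) | set(roles_ii["multi"]))
    if set(planted_ii) & all_ref_ii:
        raise GenerationError("planted class II peptide collides with a reference set")
    for pep in planted_ii:
        if any(b in pep for b in refs.cohort_nml_i) or \
                any(b in pep for b in refs.benign_multi_tissue_i):
            raise GenerationError("planted class II peptide contains a benign "
                                  "class I ligand")

    return LigandomeScenario(
        spec=spec, patient=patient, matrices=matrices,
        tumor_classI=tumor_i, tumor_classII=tumor_ii, refs=refs,
        planted_classI=planted_i, planted_classII=planted_ii,
        nested_pair_peptides=nested_i, classI_containing_ii=containing_ii)


# ---------------------------------------------------------------------------
# Somatic variant tables
# ---------------------------------------------------------------------------

@dataclass
class VariantTableSpec:
    seed: int = 0
    n_pass: int = 5           # variants passing every filter
    n_low_depth: int = 3      # tumor depth <= 25
    n_normal_contaminated: int = 3
    n_multi_locus: int = 2
    n_synonymous: int = 2
    depth_mean: float = 60.0  # passing variants: depth well above threshold


def gen_variant_table(spec: VariantTableSpec) -> pd.DataFrame:
    """A variant table with planted filter structure; the ``expected_kept``
    column records the planted truth."""
    rng = _rng(spec.seed, "variants")
    rows = []

    def base_row(i, kind):
        return {
            "gene": f"GENE{i:03d}", "transcript": f"ENST{i:07d}",
            "protein_change": f"{AMINO_ACIDS[rng.integers(20)]}"
                              f"{int(rng.integers(20, 200))}"
                              f"{AMINO_ACIDS[rng.integers(20)]}",
            "tumor_depth": 0, "normal_alt_reads": 0,
            "consequence": "missense", "multi_locus": "0",
            "expected_kept": False, "planted_kind": kind,
        }

    i = 0
    for _ in range(spec.n_pass):
        row = base_row(i, "pass")
        row["tumor_depth"] = int(26 + rng.poisson(spec.depth_mean - 26))
        row["expected_kept"] = True
        rows.append(row); i += 1
    for _ in range(spec.n_low_depth):
        row = base_row(i, "low_depth")
        row["tumor_depth"] = int(rng.integers(1, 26))
        rows.append(row); i += 1
    for _ in range(spec.n_normal_contaminated):
        row = base_row(i, "normal_contaminated")
        row["tumor_depth"] = int(26 + rng.poisson(spec.depth_mean - 26))
        row["normal_alt_reads"] = int(rng.integers(1, 10))
        rows.append(row); i += 1
    for _ in range(spec.n_multi_locus):
        row = base_row(i, "multi_locus")
        row["tumor_depth"] = int(26 + rng.poisson(spec.depth_mean - 26))
        row["multi_locus"] = "1"
        rows.append(row); i += 1
    for _ in range(spec.n_synonymous):
        row = base_row(i, "synonymous")
        row["tumor_depth"] = int(26 + rng.poisson(spec.depth_mean - 26))
        row["consequence"] = "synonymous"
        rows.append(row); i += 1
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ICS panels
# ---------------------------------------------------------------------------

@dataclass
class IcsSpec:
    """Planted ICS scenario.

    ``planted`` maps stimulus name -> intended longitudinal class (values of
    :class:`~episelect.ics.TimecourseClass`). Background marker percentages
    are drawn uniformly from ``background_pct`` (percent units). A planted
    positive marker sits ``effect_delta_pct`` percentage points above its
    control — comfortably above both calling criteria for any background in
    the band — so the response magnitude of a positive timepoint is
    ``n_positive_markers x effect_delta_pct`` up to count rounding.
    'Enhanced' stimuli scale the post-treatment delta by
    ``enhancement_ratio``; stable pre-existing ones by ``not_enhanced_ratio``
    (close to 1, below the 2-fold enhancement rule).
    """

    seed: int = 0
    patient_id: str = "SYN01"
    subset: str = "CD4"
    timepoints: tuple[str, ...] = ("pre", "1M", "4M")
    planted: dict = field(default_factory=lambda: {
        "PEP_INDUCED": "induced",
        "PEP_ENHANCED": "enhanced",
        "PEP_STABLE": "pre_existing_not_enhanced",
        "PEP_ABSENT": "absent",
    })
    n_positive_markers: int = 3
    background_pct: tuple[float, float] = (0.05, 0.15)
    subset_total_range: tuple[int, int] = (15000, 30000)
    effect_delta_pct: float = 1.0
    enhancement_ratio: float = 3.0
    not_enhanced_ratio: float = 1.1
    min_fold: float = 2.0
    min_excess: int = 20

    def validate(self) -> None:
        lo_total, hi_total = self.subset_total_range
        hi_pct = self.background_pct[1]
        if self.effect_delta_pct < (self.min_fold - 1) * hi_pct:
            raise GenerationError(
                "effect_delta_pct too small to guarantee the fold criterion "
                "over the background band")
        worst_excess = (self.effect_delta_pct * lo_total
                        - hi_pct * (hi_total - lo_total)) / 100.0
        if worst_excess < self.min_excess:
            raise GenerationError(
                "effect_delta_pct too small to guarantee the cell-excess "
                "criterion over the acquisition-size range")
        if self.n_positive_markers < 2:
            raise GenerationError("positive stimuli need >= 2 positive markers")
        if self.enhancement_ratio < 2.0:
            raise GenerationError("enhancement_ratio must be >= the 2-fold rule")
        if not 0 < self.not_enhanced_ratio < 2.0:
            raise GenerationError("not_enhanced_ratio must stay below the "
                                  "2-fold enhancement rule")


def gen_ics_panel(spec: IcsSpec) -> tuple[pd.DataFrame, dict[str, str]]:
    """Generate a long-format ICS event-count table plus truth labels.

    One DMSO control per timepoint; planted positive (stimulus, timepoint)
    cells exceed both positivity criteria on ``n_positive_markers`` markers,
    planted negatives are clamped below the fold criterion and the excess
    criterion. Returns (table, {stimulus: planted class}).
    """
    spec.validate()
    rng = _rng(spec.seed, "ics")
    rows = []
    controls: dict[str, dict[str, int]] = {}
    totals: dict[str, int] = {}
    lo_pct, hi_pct = spec.background_pct

    for tp in spec.timepoints:
        total = int(rng.integers(*spec.subset_total_range))
        totals[tp] = total
        events = {}
        for marker in MARKERS:
            pct = rng.uniform(lo_pct, hi_pct)
            events[marker] = max(1, int(round(pct / 100.0 * total)))
        controls[tp] = events
        for marker in MARKERS:
            rows.append({"patient": spec.patient_id, "timepoint": tp,
                         "timepoint_order": spec.timepoints.index(tp),
                         "stimulus": "DMSO", "subset": spec.subset,
                         "marker": marker, "positive_events": events[marker],
                         "subset_total": total})

    def negative_events(tp: str, marker: str, total: int) -> int:
        ctrl = controls[tp][marker]
        ctrl_pct = 100.0 * ctrl / totals[tp]
        # stay below both criteria: < min_fold x control pct and < +min_excess
        cap_fold = int(np.floor((spec.min_fold * ctrl_pct * 0.9) / 100.0 * total))
        cap_excess = ctrl + spec.min_excess - 1
        cap = max(0, min(cap_fold, cap_excess))
        return int(rng.integers(0, cap + 1))

    def positive_events(tp: str, marker: str, total: int, scale: float) -> int:
        ctrl = controls[tp][marker]
        ctrl_pct = 100.0 * ctrl / totals[tp]
        target_pct = ctrl_pct + spec.effect_delta_pct * scale
        return min(int(round(target_pct / 100.0 * total)), total)

    truth: dict[str, str] = {}
    for stimulus, cls in spec.planted.items():
        truth[stimulus] = cls
        pre = spec.timepoints[0]
        for tp in spec.timepoints:
            total = int(rng.integers(*spec.subset_total_range))
            if cls == "absent":
                positive_here, scale = False, 1.0
            elif cls == "induced":
                positive_here, scale = tp != pre, 1.0
            elif cls == "enhanced":
                positive_here = True
                scale = 1.0 if tp == pre else spec.enhancement_ratio
            else:  # pre_existing_not_enhanced
                positive_here = True
                scale = 1.0 if tp == pre else spec.not_enhanced_ratio
            for m_idx, marker in enumerate(MARKERS):
                if positive_here and m_idx < spec.n_positive_markers:
                    n = positive_events(tp, marker, total, scale)
                else:
                    n = negative_events(tp, marker, total)
                rows.append({"patient": spec.patient_id, "timepoint": tp,
                             "timepoint_order": spec.timepoints.index(tp),
                             "stimulus": stimulus, "subset": spec.subset,
                             "marker": marker, "positive_events": n,
                             "subset_total": total})
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# IHC tables
# ---------------------------------------------------------------------------

@dataclass
class IhcSpec:
    """Two patient groups with negative-binomial per-HPF counts.

    ``mean_shift`` is added to the treated group's mean; ``dispersion`` is
    the negative binomial size parameter (smaller = more overdispersed).
    """

    seed: int = 0
    marker: str = "CD8"
    compartment: Compartment = Compartment.TUMOR_CENTER
    n_group_a: int = 8            # RFA + surgery
    n_group_b: int = 7            # surgery only
    mean_a: float = 40.0
    mean_shift: float = 0.0
    dispersion: float = 8.0
    n_hpf: int = 5


def gen_ihc_table(spec: IhcSpec) -> tuple[pd.DataFrame, dict]:
    """Per-HPF positive-cell counts for two groups; returns (table, truth)."""
    rng = _rng(spec.seed, "ihc")

    def draw_counts(mu: float, n: int) -> np.ndarray:
        r = spec.dispersion
        p = r / (r + mu)
        return rng.negative_binomial(r, p, size=n)

    rows = []
    for g, (group, n_patients, mu) in enumerate([
            (PatientGroup.RFA_PLUS_SURGERY, spec.n_group_a,
             spec.mean_a + spec.mean_shift),
            (PatientGroup.SURGERY_ONLY, spec.n_group_b, spec.mean_a)]):
        for k in range(n_patients):
            counts = draw_counts(mu, spec.n_hpf)
            rows.append({
                "patient": f"{'R' if g == 0 else 'S'}{k + 1:02d}",
                "group": group.value, "marker": spec.marker,
                "compartment": spec.compartment.value,
                **{f"hpf{j + 1}": int(c) for j, c in enumerate(counts)},
            })
    truth = {"mean_rfa_group": spec.mean_a + spec.mean_shift,
             "mean_surgery_group": spec.mean_a,
             "mean_shift": spec.mean_shift}
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# Scenario directory writer
# ---------------------------------------------------------------------------

def write_scenario(directory, spec: LigandomeSpec | None = None,
                   variant_spec: VariantTableSpec | None = None,
                   ics_spec: IcsSpec | None = None,
                   ihc_spec: IhcSpec | None = None):
    """Write a complete, self-contained scenario directory.

    Produces every input file a patient run consumes (tumor ligand tables,
    reference compendium, score matrices, variant table, ICS panel, IHC
    table), the planted-truth files, and a ready-to-run ``config.yaml``.
    Returns the generated :class:`LigandomeScenario`.
    """
    from pathlib import Path

    from .binding import write_matrix
    from .core import write_ligand_table
    from .pipeline import RunConfig

    directory = Path(directory)
    (directory / "refs").mkdir(parents=True, exist_ok=True)
    (directory / "matrices").mkdir(exist_ok=True)
    (directory / "truth").mkdir(exist_ok=True)

    spec = spec or LigandomeSpec()
    scenario = gen_ligandome_scenario(spec)
    write_ligand_table(scenario.tumor_classI, directory / "tumor_classI.tsv",
                       provenance="synthetic")
    write_ligand_table(scenario.tumor_classII, directory / "tumor_classII.tsv",
                       provenance="synthetic")
    ref_paths = {}
    for role in ("autologous_nml_i", "cohort_nml_i", "nmt_colon_i",
                 "benign_multi_tissue_i", "autologous_nml_ii",
                 "cohort_nml_ii", "nmt_colon_ii", "benign_multi_tissue_ii",
                 "classII_ligands_for_nesting"):
        ligands = getattr(scenario.refs, role)
        path = directory / "refs" / f"{role}.tsv"
        write_ligand_table(ligands, path, provenance="synthetic")
        ref_paths[role] = f"refs/{role}.tsv"
    for allele in scenario.patient.class_i_alleles:
        for length in scenario.matrices.lengths_for([allele]):
            matrix = scenario.matrices.get(allele, length)
            safe = allele.replace("*", "")
            write_matrix(matrix, directory / "matrices" / f"{safe}_{length}.tsv")

    (directory / "truth" / "planted_classI.txt").write_text(
        "\n".join(scenario.planted_classI) + "\n")
    (directory / "truth" / "planted_classII.txt").write_text(
        "\n".join(scenario.planted_classII) + "\n")

    paths = {"tumor_classI": "tumor_classI.tsv",
             "tumor_classII": "tumor_classII.tsv",
             "matrices_dir": "matrices", "refs": ref_paths}

    if variant_spec is not None:
        table = gen_variant_table(variant_spec)
        table.drop(columns=["expected_kept", "planted_kind"]).to_csv(
            directory / "variants.tsv", sep="\t", index=False,
            lineterminator="\n")
        table.to_csv(directory / "truth" / "variants_truth.tsv", sep="\t",
                     index=False, lineterminator="\n")
    if ics_spec is not None:
        panel, truth = gen_ics_panel(ics_spec)
        panel.to_csv(directory / "ics.tsv", sep="\t", index=False,
                     lineterminator="\n")
        pd.Series(truth, name="planted_class").rename_axis("stimulus") \
            .reset_index().to_csv(directory / "truth" / "ics_truth.tsv",
                                  sep="\t", index=False, lineterminator="\n")
        paths["ics_table"] = "ics.tsv"
    if ihc_spec is not None:
        table, truth = gen_ihc_table(ihc_spec)
        table.to_csv(directory / "ihc.tsv", sep="\t", index=False,
                     lineterminator="\n")
        pd.Series(truth).rename_axis("key").reset_index(name="value").to_csv(
            directory / "truth" / "ihc_truth.tsv", sep="\t", index=False,
            lineterminator="\n")

    config = RunConfig(patient_id=spec.patient_id,
                       alleles=tuple(scenario.patient.class_i_alleles),
                       paths=paths, seed=spec.seed)
    config.to_yaml(directory / "config.yaml")
    return scenario
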