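"""Per-patient orchestration: configuration, stage wiring, report tables.

``run_patient`` ties the stages together for one patient: read the tumor
ligandomes and reference compendia, run the class I and class II selection
cascades, predict variant-derived 15-mer long peptides, call ICS responses,
and emit deterministic delimited-text reports (step traces mirroring the
selection funnel, candidate tables with provenance, a per-sample summary
with binder percentages). Stages whose inputs are not configured are
skipped; every threshold has the conventional default (relative score 50/60,
IC50 500 nM, tumor depth 25 reads, 10 split reads, fusion probability 0.8,
ICS fold 2 / 20 cells / enhancement fold 2, candidate cap 6-9).

Reports are byte-identical across reruns with the same config and inputs:
orderings are fixed, percentages round half-up to one decimal, means to the
nearest integer.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd
import yaml

from ._rounding import round_half_up
from .binding import (MatrixRegistry, TableLookupPredictor, load_matrix_dir)
from .cascade import (CascadeConfig, CascadeResult, ReferenceCompendium,
                      run_classI_cascade, run_classII_cascade)
from .core import HlaClass, PatientHLA, read_ligand_table
from .curation import CurationRecord, RankingWeights, rank_candidates
from .errors import ConfigurationError, EpiselectError
from .ics import call_panel
from .neoantigen import (filter_fusions, filter_somatic_variants,
                         predict_long_peptides, read_fusion_table,
                         read_protein_fasta, read_variant_table)

_REF_ROLES_I = ("autologous_nml_i", "cohort_nml_i", "nmt_colon_i",
                "benign_multi_tissue_i")
_REF_ROLES_II = ("autologous_nml_ii", "cohort_nml_ii", "nmt_colon_ii",
                 "benign_multi_tissue_ii", "classII_ligands_for_nesting")


@dataclass
class Thresholds:
    syfpeithi: float = 50.0
    syfpeithi_final: float = 60.0
    ic50_nm: float = 500.0
    tumor_depth: int = 25
    split_reads: int = 10
    fusion_probability: float = 0.8
    ics_fold: float = 2.0
    ics_excess_cells: int = 20
    enhancement_fold: float = 2.0


@dataclass
class RunConfig:
    """One patient's run: identity, input paths, thresholds, switches."""

    patient_id: str
    alleles: tuple[str, ...] = ()
    paths: dict = field(default_factory=dict)
    thresholds: Thresholds = field(default_factory=Thresholds)
    binder_rule: str = "or"
    motif_mode: str = "matrix"
    disabled_steps_classI: tuple[str, ...] = ()
    disabled_steps_classII: tuple[str, ...] = ()
    candidate_cap: int = 9
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict) or "patient_id" not in raw:
            raise ConfigurationError(f"{path}: config must define patient_id")
        thresholds = Thresholds(**raw.pop("thresholds", {}))
        known = {f for f in cls.__dataclass_fields__}  # type: ignore[attr-defined]
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"{path}: unknown config keys {sorted(unknown)}")
        raw["alleles"] = tuple(raw.get("alleles", ()))
        raw["disabled_steps_classI"] = tuple(raw.get("disabled_steps_classI", ()))
        raw["disabled_steps_classII"] = tuple(raw.get("disabled_steps_classII", ()))
        return cls(thresholds=thresholds, **raw)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["alleles"] = list(self.alleles)
        data["disabled_steps_classI"] = list(self.disabled_steps_classI)
        data["disabled_steps_classII"] = list(self.disabled_steps_classII)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


@dataclass
class ReportBundle:
    """The tables produced by one patient run."""

    classI_trace: Optional[pd.DataFrame] = None
    classII_trace: Optional[pd.DataFrame] = None
    classI_candidates: Optional[pd.DataFrame] = None
    classII_candidates: Optional[pd.DataFrame] = None
    long_peptides: Optional[pd.DataFrame] = None
    ics_calls: Optional[pd.DataFrame] = None
    summary: Optional[pd.DataFrame] = None

    def tables(self) -> dict[str, pd.DataFrame]:
        return {name: df for name, df in vars(self).items() if df is not None}

    def write(self, out_dir: str | Path) -> list[Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        written = []
        for name, df in sorted(self.tables().items()):
            path = out_dir / f"{name}.tsv"
            df.to_csv(path, sep="\t", index=False, lineterminator="\n")
            written.append(path)
        return written


def _trace_table(result: CascadeResult, n_input: int) -> pd.DataFrame:
    rows = [{"step": "input", "retained": n_input}]
    rows += [{"step": name, "retained": n} for name, n in result.counts()]
    return pd.DataFrame(rows)


def _candidate_table(result: CascadeResult) -> pd.DataFrame:
    rows = []
    for rank, seq in enumerate(result.final_candidates.sequences(), start=1):
        rec = result.final_candidates.get(seq)
        rows.append({
            "rank": rank, "sequence": seq, "patient": rec.patient_id,
            "hla_class": rec.hla_class.value,
            "source_proteins": ";".join(rec.source_proteins),
            "multiplicity": result.final_candidates.multiplicity[seq],
            "provenance": "cascade:" + ">".join(n for n, _ in result.counts()),
        })
    return pd.DataFrame(
        rows, columns=["rank", "sequence", "patient", "hla_class",
                       "source_proteins", "multiplicity", "provenance"])


def _load_refs(paths: Mapping[str, str], base: Path) -> ReferenceCompendium:
    kwargs = {}
    for role in _REF_ROLES_I + _REF_ROLES_II:
        p = paths.get(role)
        if p is None:
            continue
        hla_class = HlaClass.I if role.endswith("_i") else HlaClass.II
        ligands, _ = read_ligand_table(base / p, hla_class)
        kwargs[role] = ligands
    return ReferenceCompendium(**kwargs)


def run_patient(config: RunConfig, out_dir: str | Path | None = None
                ) -> ReportBundle:
    """Run every configured stage for one patient.

    ``config.paths`` keys (all optional unless a stage needs them):
    ``tumor_classI``, ``tumor_classII``, ``matrices_dir``,
    ``predictor_table``, ``refs`` (mapping of reference role -> path),
    ``variants``, ``fusions``, ``proteins_fasta``, ``ics_table``,
    ``base_dir`` (prefix for relative paths). Writes the report tables to
    ``out_dir`` when given.
    """
    paths = dict(config.paths)
    base = Path(paths.pop("base_dir", "."))
    thr = config.thresholds
    bundle = ReportBundle()
    summary_rows = []

    matrices = MatrixRegistry()
    if "matrices_dir" in paths:
        matrices = load_matrix_dir(base / paths["matrices_dir"])
    predictor = None
    if "predictor_table" in paths:
        predictor = TableLookupPredictor.from_file(base / paths["predictor_table"])
    refs = _load_refs(paths.get("refs", {}), base)
    patient = PatientHLA(config.patient_id, config.alleles) if config.alleles \
        else None

    cascade_cfg = CascadeConfig(
        syfpeithi_threshold=thr.syfpeithi, final_threshold=thr.syfpeithi_final,
        ic50_threshold=thr.ic50_nm, binder_rule=config.binder_rule,
        motif_mode=config.motif_mode)

    if "tumor_classI" in paths:
        if patient is None:
            raise ConfigurationError("class I cascade requires patient alleles")
        tumor_i, _ = read_ligand_table(base / paths["tumor_classI"], HlaClass.I)
        cfg_i = CascadeConfig(**{**vars(cascade_cfg),
                                 "disabled_steps": config.disabled_steps_classI})
        try:
            res_i = run_classI_cascade(tumor_i, patient, refs, matrices,
                                       predictor, cfg_i)
        except EpiselectError as exc:
            raise ConfigurationError(
                f"class I cascade failed for patient {config.patient_id}: {exc}"
            ) from exc
        bundle.classI_trace = _trace_table(res_i, len(tumor_i))
        bundle.classI_candidates = _candidate_table(res_i)
        binder_n = dict(res_i.counts()).get("binders")
        summary_rows.append({
            "sample": f"{config.patient_id}-tumor-classI",
            "peptides": len(tumor_i),
            "binders": binder_n if binder_n is not None else "",
            "binders_percent": (round_half_up(100 * binder_n / len(tumor_i), 1)
                                if binder_n is not None and len(tumor_i) else 0.0),
            "final_candidates": len(res_i.final_candidates),
        })

    if "tumor_classII" in paths:
        tumor_ii, _ = read_ligand_table(base / paths["tumor_classII"], HlaClass.II)
        cfg_ii = CascadeConfig(**{**vars(cascade_cfg),
                                  "disabled_steps": config.disabled_steps_classII})
        res_ii = run_classII_cascade(tumor_ii, refs, cfg_ii,
                                     patient_id=config.patient_id)
        bundle.classII_trace = _trace_table(res_ii, len(tumor_ii))
        bundle.classII_candidates = _candidate_table(res_ii)
        summary_rows.append({
            "sample": f"{config.patient_id}-tumor-classII",
            "peptides": len(tumor_ii), "binders": "", "binders_percent": "",
            "final_candidates": len(res_ii.final_candidates),
        })

    if "variants" in paths and "proteins_fasta" in paths:
        if patient is None:
            raise ConfigurationError("neoantigen prediction requires patient alleles")
        variants = read_variant_table(base / paths["variants"])
        proteins = read_protein_fasta(base / paths["proteins_fasta"])
        kept = filter_somatic_variants(variants, min_depth=thr.tumor_depth)
        lp_rows = []
        for v in kept:
            if v.gene not in proteins:
                continue
            for lp in predict_long_peptides(v, proteins[v.gene], patient,
                                            matrices, thr.syfpeithi_final):
                lp_rows.append({
                    "sequence": lp.sequence,
                    "wildtype": lp.wildtype_counterpart or "",
                    "gene": v.gene,
                    "span": f"{lp.span[0]}-{lp.span[1]}",
                    "window": f"{lp.window_span[0]}-{lp.window_span[1]}",
                    "provenance": "variant:"
                                  f"{v.protein_change.ref}{v.protein_change.position}"
                                  f"{v.protein_change.alt}",
                })
        if "fusions" in paths:
            fusions = filter_fusions(read_fusion_table(base / paths["fusions"]),
                                     min_split=thr.split_reads,
                                     min_prob=thr.fusion_probability)
            for f in fusions:
                lp_rows.append({
                    "sequence": f.junction_peptide_context,
                    "wildtype": "", "gene": f"{f.gene_5p}-{f.gene_3p}",
                    "span": "", "window": "", "provenance": "fusion",
                })
        bundle.long_peptides = pd.DataFrame(
            lp_rows, columns=["sequence", "wildtype", "gene", "span",
                              "window", "provenance"])

    if "ics_table" in paths:
        panel = pd.read_csv(base / paths["ics_table"], sep="\t")
        bundle.ics_calls = call_panel(panel, min_fold=thr.ics_fold,
                                      min_excess=thr.ics_excess_cells,
                                      enhancement_fold=thr.enhancement_fold)

    if summary_rows:
        bundle.summary = pd.DataFrame(summary_rows)

    if out_dir is not None:
        bundle.write(out_dir)
    return bundle


def curate_candidates(cascade_result: CascadeResult,
                      records: list[CurationRecord],
                      weights: RankingWeights | None = None,
                      cap: int = 9) -> pd.DataFrame:
    """Rank curation records (variant-derived first) and return a report table."""
    ranked = rank_candidates(records, weights, cap)
    return pd.DataFrame([{
        "rank": r.rank, "sequence": r.peptide, "hla_class": r.hla_class.value,
        "gene": r.source_gene, "log2_fc": r.fc,
        "cohort_frequency": r.cohort_frequency,
        "tumor_association": r.tumor_association,
        "from_variant": r.from_variant,
    } for r in ranked])


def summarize_table1(samples: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Per-sample binder percentages and per-tissue mean peptide yields.

    ``samples`` needs columns sample, tissue, peptides, binders (binders may
    be missing/NaN for sample types without binder annotation). Returns the
    per-sample table with a ``binders_percent`` column (one decimal,
    half-up) and a per-tissue mean peptide count (nearest integer, half-up).
    """
    required = {"sample", "tissue", "peptides"}
    missing = required - set(samples.columns)
    if missing:
        raise ConfigurationError(f"summary table missing column(s) {sorted(missing)}")
    out = samples.copy()

    def pct(row):
        binders = row.get("binders")
        if binders is None or pd.isna(binders) or row["peptides"] == 0:
            return float("nan") if row["peptides"] else 0.0
        return round_half_up(100.0 * binders / row["peptides"], 1)

    out["binders_percent"] = out.apply(pct, axis=1)
    means = (out.groupby("tissue")["peptides"].mean()
             .map(lambda m: int(round_half_up(m, 0))))
    return out, means
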