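# episelect

Patient-individualized selection of tumor antigen targets from HLA
ligandomes, with neoepitope design, T cell response calling and
immunohistochemistry scoring.

## The problem

Thermal ablation of a tumor lesion can act as an *in situ* vaccination:
released tumor antigens may prime or boost T cell responses that also reach
distant lesions. Testing that hypothesis in an individual patient requires
choosing, from thousands of HLA-presented peptides eluted from their tumor,
the handful that are plausibly tumor-specific and worth synthesizing for
immunological assays — and then reading out whether T cells actually
responded. `episelect` implements that computational chain for
immunopeptidomics analysts:

- **Ligandome set algebra** — deduplicated peptide sets with exact and
  substring-containment subtraction, the primitive behind tumor-vs-benign
  comparison (`episelect.core`).
- **Binding assessment** — additive position-specific scoring matrices
  (PSSMs) with the *relative score* `100 · s / s_max` (percent of the
  maximal allelic score), combined with a pluggable IC50 affinity-predictor
  contract; a peptide is a binder when it exceeds a relative-score threshold
  (default strict >50%) or an IC50 cutoff (default <500 nM) on ≥1 patient
  allele (`episelect.binding`).
- **Selection cascades** — the seven-step HLA class I funnel (binders →
  motif confirmation → subtraction of autologous/cohort non-malignant liver,
  non-malignant colon and a multi-tissue benign compendium → removal of
  peptides nested in class II ligands → relative score >60%) and the
  five-step class II funnel, each with a per-step retained-count trace
  (`episelect.cascade`).
- **Neoepitope prediction** — somatic variant and fusion filtering (depth
  >25 reads, zero alt reads in normal, unambiguous locus; >10 split reads
  and probability >0.8), protein-level mutation application, scanning of
  mutation-spanning windows for predicted binders, and extension to 15-mer
  long peptides with wildtype counterparts (`episelect.neoantigen`).
- **Curation metrics** — CPM normalization, log2 tumor/normal fold change,
  cohort identification frequency (nested length variants count for class
  II), and deterministic ranking with variant-derived candidates first and a
  6–9 peptide cap (`episelect.curation`).
- **ICS response calling** — the three positivity criteria (≥2-fold over the
  DMSO background, ≥20 excess cells, ≥2 of 5 markers among IFNγ, TNF, IL-2,
  CD107a, CD154) and longitudinal classification into absent / induced /
  pre-existing (enhanced or not) (`episelect.ics`).
- **IHC scoring** — immunoreactive score (positivity bin 0–4 × intensity
  0–3, range 0–12), per-HPF means, hot-spot selection, Mann-Whitney group
  comparison (`episelect.ihc`).
- **Synthetic data** — seeded generators for every input above with planted
  ground truth, so the full pipeline is testable offline
  (`episelect.synth`).

## Worked example

```bash
python examples/01_ligand_selection_cascade.py
```

```
tumor class I peptides: 505 (20 planted tumor-exclusive binders)

class I selection funnel (step, retained):
  binders                    77
  motif                      77
  subtract_nml               49
  subtract_nmt               40
  subtract_benign_multi      25
  remove_classII_nested      20
  strong_binders             20

recovered 20 candidates; equals planted truth: True
```

The funnel starts from all 505 eluted peptides: 77 bind at least one patient
allele, benign-tissue subtraction strips the shared peptides step by step,
the nesting filter removes the five class I peptides embedded in class II
ligands, and the >60% relative-score filter leaves exactly the 20 planted
tumor-exclusive strong binders — zero false positives or negatives.

The other scripts in `examples/` demonstrate neoepitope 15-mer design,
expression-based curation, ICS response calling and IHC scoring, each
printing what the numbers mean.

A thin CLI mirrors the library (`episelect synth | select | neo | curate |
ics | ihc | run | report`); run `episelect --help`.

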