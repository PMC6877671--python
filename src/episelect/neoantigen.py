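"""Prediction of mutated HLA ligands from somatic variant and fusion calls.

The pipeline consumes protein-level somatic variant calls (SNVs/InDels) and
gene-fusion calls with read-support attributes, filters them by depth and
support rules, applies the protein change to the reference protein, scans
every peptide window spanning a mutated residue for predicted HLA class I
binders (matrix relative score above a threshold on >= 1 patient allele),
and extends each retained binder window to a 15-mer synthetic long peptide
with its wildtype counterpart — long enough to be processed for both HLA
class I and class II presentation when used as a vaccine or stimulation
peptide.

Variant filtering rules (all strict inequalities where printed as such):
non-synonymous consequence, tumor depth > 25 reads, zero alt-supporting
reads in matched normal tissue, unambiguous transcript locus; fusions need
> 10 split reads and caller probability > 0.8, and at least one partner
gene on the (user-supplied) relevance whitelist when one is given.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio import SeqIO

from .binding import MatrixRegistry, relative_score_raw
from .core import PatientHLA, validate_peptide
from .errors import EpiselectError, FormatError, UnextendableError


class ChangeKind(str, Enum):
    SUBSTITUTION = "substitution"
    INFRAME_INS = "inframe_ins"
    INFRAME_DEL = "inframe_del"
    FRAMESHIFT = "frameshift"


@dataclass
class ProteinChange:
    """A protein-level edit. ``position`` is 1-based.

    substitution: ``ref`` residue(s) at ``position`` replaced by ``alt``.
    inframe_ins: ``alt`` inserted immediately after ``position`` (whose
    residue must equal ``ref``). inframe_del: ``ref`` residues starting at
    ``position`` removed. frameshift: the suffix from ``position`` onward
    replaced by ``alt`` (the explicitly provided alternate C-terminal tail).
    """

    position: int
    ref: str
    alt: str
    kind: ChangeKind = ChangeKind.SUBSTITUTION


@dataclass
class SomaticVariant:
    gene: str
    transcript_ids: tuple[str, ...]
    protein_change: ProteinChange
    tumor_depth: int
    normal_alt_reads: int
    consequence: str = "missense"          # non-synonymous consequence required
    multi_locus: bool = False              # transcript maps to >1 genetic locus


@dataclass
class FusionEvent:
    gene_5p: str
    gene_3p: str
    split_reads: int
    probability: float
    junction_peptide_context: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError(
                f"fusion probability {self.probability} outside [0, 1]"
            )


NON_SYNONYMOUS = {
    "missense", "missense_variant", "nonsynonymous", "non-synonymous",
    "inframe_insertion", "inframe_deletion", "frameshift", "frameshift_variant",
    "stop_lost",
}


def filter_somatic_variants(variants: Iterable[SomaticVariant],
                            min_depth: int = 25,
                            gene_whitelist: Sequence[str] | None = None
                            ) -> list[SomaticVariant]:
    """Keep variants passing the depth / normal-contamination / locus rules.

    ``min_depth`` is total tumor read depth at the locus and the comparison
    is strict (> 25 keeps 26, rejects 25). "Undetectable in normal" means
    zero alt-supporting normal reads.
    """
    wl = {g.upper() for g in gene_whitelist} if gene_whitelist else None
    kept = []
    for v in variants:
        if v.consequence.lower() not in NON_SYNONYMOUS:
            continue
        if not (v.tumor_depth > min_depth and v.normal_alt_reads == 0
                and not v.multi_locus):
            continue
        if wl is not None and v.gene.upper() not in wl:
            continue
        kept.append(v)
    return kept


def filter_fusions(fusions: Iterable[FusionEvent], min_split: int = 10,
                   min_prob: float = 0.8,
                   gene_whitelist: Sequence[str] | None = None
                   ) -> list[FusionEvent]:
    """Keep fusions with > ``min_split`` split reads and probability > ``min_prob``.

    When a whitelist is given, at least one partner gene must be on it."""
    wl = {g.upper() for g in gene_whitelist} if gene_whitelist else None
    kept = []
    for f in fusions:
        if not (f.split_reads > min_split and f.probability > min_prob):
            continue
        if wl is not None and not ({f.gene_5p.upper(), f.gene_3p.upper()} & wl):
            continue
        kept.append(f)
    return kept


def apply_protein_change(reference_protein: str, change: ProteinChange) -> str:
    """Apply a protein-level change to a reference sequence.

    Raises :class:`EpiselectError` when the stated reference residues do not
    match the protein at the stated position (variant and protein out of
    sync). A substitution with ``alt == ref`` returns the input unchanged
    with a warning.
    """
    protein = validate_peptide(reference_protein)
    pos = change.position
    ref = change.ref.upper()
    alt = change.alt.upper() if change.alt else ""
    if not 1 <= pos <= len(protein):
        raise EpiselectError(
            f"change position {pos} outside protein of length {len(protein)}"
        )
    if change.kind in (ChangeKind.SUBSTITUTION, ChangeKind.INFRAME_DEL,
                       ChangeKind.INFRAME_INS, ChangeKind.FRAMESHIFT):
        window = protein[pos - 1: pos - 1 + len(ref)] if ref else ""
        if ref and window != ref:
            raise EpiselectError(
                f"reference mismatch at position {pos}: protein has "
                f"{window!r}, change states {ref!r}"
            )
    if change.kind is ChangeKind.SUBSTITUTION:
        if alt == ref:
            warnings.warn("substitution with alt == ref; sequence unchanged",
                          stacklevel=2)
            return protein
        return protein[:pos - 1] + alt + protein[pos - 1 + len(ref):]
    if change.kind is ChangeKind.INFRAME_INS:
        return protein[:pos] + alt + protein[pos:]
    if change.kind is ChangeKind.INFRAME_DEL:
        return protein[:pos - 1] + protein[pos - 1 + len(ref):]
    # frameshift: explicit alternate C-terminal tail replaces the suffix
    if not alt:
        raise EpiselectError("frameshift change requires an explicit alternate tail")
    return protein[:pos - 1] + alt


def mutated_positions_of(change: ChangeKind | ProteinChange, mutated_protein: str
                         ) -> list[int]:
    """1-based positions in the *mutated* protein that differ from wildtype."""
    change = change if isinstance(change, ProteinChange) else None
    if change is None:
        raise ValueError("a ProteinChange is required")
    pos = change.position
    if change.kind is ChangeKind.SUBSTITUTION:
        return list(range(pos, pos + len(change.alt)))
    if change.kind is ChangeKind.INFRAME_INS:
        return list(range(pos + 1, pos + 1 + len(change.alt)))
    if change.kind is ChangeKind.INFRAME_DEL:
        # the junction: the residue now sitting at the deletion site
        return [min(pos, len(mutated_protein))]
    return list(range(pos, len(mutated_protein) + 1))  # frameshift tail


@dataclass
class MutatedWindow:
    """A candidate class I binder window spanning >= 1 mutated residue."""

    sequence: str
    protein: str                 # gene/protein identifier
    span: tuple[int, int]        # 1-based inclusive in the mutated protein
    mutated_positions: tuple[int, ...]
    best_relative_score: float
    allele: str


@dataclass
class LongPeptide15:
    """A 15-mer synthetic long peptide around a binder window."""

    sequence: str
    protein: str
    span: tuple[int, int]            # 1-based inclusive in the mutated protein
    window_span: tuple[int, int]
    mutated_positions: tuple[int, ...]   # within the 15-mer, 1-based
    wildtype_counterpart: Optional[str] = None

    def __post_init__(self) -> None:
        if len(self.sequence) != 15:
            raise UnextendableError(
                f"long peptide must have length 15, got {len(self.sequence)}"
            )


def scan_mutated_windows(mutated_protein: str, mutated_positions: Sequence[int],
                         patient: PatientHLA, matrices: MatrixRegistry,
                         rel_threshold: float = 60.0,
                         protein_id: str = "") -> list[MutatedWindow]:
    """Enumerate all matrix-supported windows containing a mutated residue
    and keep those with relative score strictly above ``rel_threshold`` on
    at least one patient allele.

    Windows are clipped to the protein; an empty result is valid. Each
    retained window records its best-scoring allele.
    """
    protein = validate_peptide(mutated_protein)
    mut = sorted(set(int(p) for p in mutated_positions))
    if any(p < 1 or p > len(protein) for p in mut):
        raise EpiselectError("mutated position outside the mutated protein")
    out: list[MutatedWindow] = []
    for length in matrices.lengths_for(patient.class_i_alleles):
        if length > len(protein):
            continue
        for start in range(1, len(protein) - length + 2):
            end = start + length - 1
            span_mut = tuple(p for p in mut if start <= p <= end)
            if not span_mut:
                continue
            seq = protein[start - 1: end]
            best: tuple[float, str] | None = None
            for allele in patient.class_i_alleles:
                matrix = matrices.get(allele, length)
                if matrix is None:
                    continue
                rel = relative_score_raw(seq, matrix)
                if best is None or rel > best[0]:
                    best = (rel, allele)
            if best is not None and best[0] > rel_threshold:
                out.append(MutatedWindow(
                    sequence=seq, protein=protein_id, span=(start, end),
                    mutated_positions=span_mut,
                    best_relative_score=best[0], allele=best[1]))
    out.sort(key=lambda w: (-w.best_relative_score, w.span, w.sequence))
    return out


def extend_to_15mer(window: MutatedWindow, mutated_protein: str,
                    wildtype_protein: str | None = None) -> LongPeptide15:
    """Extend a binder window to a 15-mer, flanks as even as possible.

    The extra residue on an odd flank remainder goes to the C-terminal side;
    when a protein end clips one flank, the deficit shifts to the other
    side. A protein shorter than 15 residues cannot be extended.
    """
    protein = validate_peptide(mutated_protein)
    if len(protein) < 15:
        raise UnextendableError(
            f"protein of length {len(protein)} cannot yield a 15-mer"
        )
    wstart, wend = window.span
    wlen = wend - wstart + 1
    if protein[wstart - 1:wend] != window.sequence:
        raise EpiselectError(
            "window sequence does not occur at its recorded span"
        )
    flank = 15 - wlen
    if flank < 0:
        raise UnextendableError(f"window longer than 15 ({wlen})")
    left = flank // 2
    right = flank - left           # odd remainder goes C-terminal
    start = wstart - left
    end = wend + right
    if start < 1:                  # clipped at N-terminus: shift deficit right
        end += 1 - start
        start = 1
    if end > len(protein):         # clipped at C-terminus: shift deficit left
        start -= end - len(protein)
        end = len(protein)
    seq = protein[start - 1: end]
    mut_in_pep = tuple(p - start + 1 for p in window.mutated_positions
                       if start <= p <= end)
    wildtype = None
    if wildtype_protein is not None:
        wt = validate_peptide(wildtype_protein)
        if len(wt) == len(protein):  # positions align (substitution case)
            wildtype = wt[start - 1: end]
    return LongPeptide15(sequence=seq, protein=window.protein,
                         span=(start, end), window_span=(wstart, wend),
                         mutated_positions=mut_in_pep,
                         wildtype_counterpart=wildtype)


def predict_long_peptides(variant: SomaticVariant, reference_protein: str,
                          patient: PatientHLA, matrices: MatrixRegistry,
                          rel_threshold: float = 60.0) -> list[LongPeptide15]:
    """Variant -> mutated protein -> binder windows -> deduplicated 15-mers."""
    mutated = apply_protein_change(reference_protein, variant.protein_change)
    positions = mutated_positions_of(variant.protein_change, mutated)
    windows = scan_mutated_windows(mutated, positions, patient, matrices,
                                   rel_threshold, protein_id=variant.gene)
    seen: set[str] = set()
    out: list[LongPeptide15] = []
    for w in windows:
        wt = reference_protein if (
            variant.protein_change.kind is ChangeKind.SUBSTITUTION) else None
        lp = extend_to_15mer(w, mutated, wt)
        if lp.sequence not in seen:
            seen.add(lp.sequence)
            out.append(lp)
    return out


# ---------------------------------------------------------------------------
# Input readers
# ---------------------------------------------------------------------------

def read_protein_fasta(path: str | Path) -> dict[str, str]:
    """Protein sequences keyed by record id (standard multi-record FASTA)."""
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def _parse_hgvs_p(text: str) -> ProteinChange:
    """Parse a minimal HGVS-like protein-change token.

    Supported forms: ``V104L`` / ``p.V104L`` (substitution), ``K10del``,
    ``K10ins<SEQ>`` (insertion after position 10), ``R7fs<TAIL>``.
    """
    t = text.strip().removeprefix("p.")
    if "fs" in t:
        head, _, tail = t.partition("fs")
        return ProteinChange(position=int(head[1:]), ref=head[0], alt=tail,
                             kind=ChangeKind.FRAMESHIFT)
    if "del" in t:
        head = t[:t.index("del")]
        return ProteinChange(position=int(head[1:]), ref=head[0], alt="",
                             kind=ChangeKind.INFRAME_DEL)
    if "ins" in t:
        head, _, inserted = t.partition("ins")
        return ProteinChange(position=int(head[1:]), ref=head[0], alt=inserted,
                             kind=ChangeKind.INFRAME_INS)
    ref, pos, alt = t[0], t[1:-1], t[-1]
    if not pos.isdigit():
        raise FormatError(f"cannot parse protein change: {text!r}")
    return ProteinChange(position=int(pos), ref=ref, alt=alt,
                         kind=ChangeKind.SUBSTITUTION)


def read_variant_table(path: str | Path, delimiter: str | None = None
                       ) -> list[SomaticVariant]:
    """Read a delimited variant table.

    Required columns: gene, transcript, protein_change, tumor_depth,
    normal_alt_reads; optional: consequence (default missense),
    multi_locus (truthy values: 1/true/yes).
    """
    import csv as _csv
    import io as _io
    text = Path(path).read_text()
    if not text.strip():
        raise FormatError(f"{path}: empty variant table")
    delim = delimiter or ("\t" if "\t" in text.splitlines()[0] else ",")
    reader = _csv.DictReader(_io.StringIO(text), delimiter=delim)
    required = {"gene", "transcript", "protein_change", "tumor_depth",
                "normal_alt_reads"}
    missing = required - set(reader.fieldnames or [])
    if missing:
        raise FormatError(f"{path}: missing column(s) {sorted(missing)}")
    variants = []
    for row in reader:
        variants.append(SomaticVariant(
            gene=row["gene"].strip(),
            transcript_ids=tuple(row["transcript"].split(";")),
            protein_change=_parse_hgvs_p(row["protein_change"]),
            tumor_depth=int(row["tumor_depth"]),
            normal_alt_reads=int(row["normal_alt_reads"]),
            consequence=(row.get("consequence") or "missense").strip(),
            multi_locus=(row.get("multi_locus") or "").strip().lower()
            in ("1", "true", "yes"),
        ))
    return variants


def read_fusion_table(path: str | Path, delimiter: str | None = None
                      ) -> list[FusionEvent]:
    """Read a delimited fusion table with columns gene_5p, gene_3p,
    split_reads, probability and optional junction_context."""
    import csv as _csv
    import io as _io
    text = Path(path).read_text()
    if not text.strip():
        raise FormatError(f"{path}: empty fusion table")
    delim = delimiter or ("\t" if "\t" in text.splitlines()[0] else ",")
    reader = _csv.DictReader(_io.StringIO(text), delimiter=delim)
    required = {"gene_5p", "gene_3p", "split_reads", "probability"}
    missing = required - set(reader.fieldnames or [])
    if missing:
        raise FormatError(f"{path}: missing column(s) {sorted(missing)}")
    return [FusionEvent(
        gene_5p=row["gene_5p"].strip(), gene_3p=row["gene_3p"].strip(),
        split_reads=int(row["split_reads"]),
        probability=float(row["probability"]),
        junction_peptide_context=(row.get("junction_context") or "").strip(),
    ) for row in reader]
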