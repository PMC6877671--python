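"""Core domain types and set algebra for HLA ligandome analysis.

An HLA *ligandome* is the set of peptides eluted from the HLA molecules of a
tissue sample and identified by tandem mass spectrometry. The selection
cascades in this package are built from a small number of primitives defined
here: validated peptide sequences, ligand records with tissue/patient
provenance, deduplicated ligand sets, and subtraction of one peptide
collection from another — either by exact sequence identity or by contiguous
substring containment (the "length variant" relation relevant for HLA class
II ligands, whose open binding groove yields nested sets of peptides sharing
a core).

Class-specific length conventions follow standard immunopeptidomics
practice: 8–12 residues for HLA class I, 9–25 for class II.
"""

from __future__ import annotations

import csv
import io
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from .errors import AlphabetError, FormatError

#: The 20 canonical amino-acid one-letter codes.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)

#: Accepted peptide length ranges per HLA class (inclusive).
CLASS_I_LENGTHS = (8, 12)
CLASS_II_LENGTHS = (9, 25)


class Tissue(str, Enum):
    """Tissue origin of an eluted peptide."""

    TUMOR = "tumor"
    NML = "NML"  # non-malignant liver
    NMT = "NMT"  # non-malignant (colon) tissue
    BENIGN_OTHER = "benign_other"

    @classmethod
    def parse(cls, value: str) -> "Tissue":
        v = value.strip()
        for member in cls:
            if member.value.lower() == v.lower() or member.name.lower() == v.lower():
                return member
        raise FormatError(f"unknown tissue label: {value!r}")


class HlaClass(str, Enum):
    """HLA class of the presenting molecule."""

    I = "I"
    II = "II"

    @property
    def length_range(self) -> tuple[int, int]:
        return CLASS_I_LENGTHS if self is HlaClass.I else CLASS_II_LENGTHS


class SubtractMode(str, Enum):
    """How a reference collection removes peptides from a query set.

    ``EXACT``
        remove query peptides whose sequence equals a reference sequence.
    ``QUERY_WITHIN_REFERENCE``
        remove query peptides that occur as a contiguous substring of any
        reference sequence (e.g. a class I 9-mer nested inside a longer
        class II ligand).
    ``REFERENCE_WITHIN_QUERY``
        remove query peptides that contain any reference sequence as a
        contiguous substring.
    """

    EXACT = "exact"
    QUERY_WITHIN_REFERENCE = "query_within_reference"
    REFERENCE_WITHIN_QUERY = "reference_within_query"


def validate_peptide(sequence: str) -> str:
    """Uppercase and validate a peptide string.

    Raises :class:`AlphabetError` for empty strings or characters outside the
    canonical 20-letter alphabet. Isoleucine and leucine are distinct
    residues here: identification tables are taken at face value.
    """
    seq = sequence.strip().upper()
    if not seq:
        raise AlphabetError("empty peptide sequence")
    bad = set(seq) - _AA_SET
    if bad:
        raise AlphabetError(
            f"non-amino-acid character(s) {sorted(bad)} in sequence {sequence!r}"
        )
    return seq


def is_nested(a: str, b: str) -> bool:
    """True iff one sequence is a contiguous substring of the other.

    Equality counts as nested. This is the length-variant relation used for
    class II ligands.
    """
    a = validate_peptide(a)
    b = validate_peptide(b)
    return a in b or b in a


@dataclass
class LigandRecord:
    """One eluted peptide with its provenance."""

    peptide: str
    patient_id: str = ""
    tissue: Tissue = Tissue.TUMOR
    hla_class: HlaClass = HlaClass.I
    source_proteins: tuple[str, ...] = ()
    sample_meta: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.peptide = validate_peptide(self.peptide)


@dataclass
class IngestLog:
    """Bookkeeping for a table ingest: what was kept, dropped and why."""

    n_rows: int = 0
    n_kept: int = 0
    n_length_dropped: int = 0
    n_alphabet_rejected: int = 0
    n_duplicates: int = 0
    rejected_rows: list[tuple[int, str]] = field(default_factory=list)


class LigandSet:
    """A deduplicated, insertion-ordered collection of ligand records.

    Identity is the peptide sequence string; the first-seen record's metadata
    is kept and a multiplicity counter records how often each sequence was
    added. All records share one HLA class.
    """

    def __init__(self, hla_class: HlaClass = HlaClass.I,
                 records: Iterable[LigandRecord] | None = None):
        self.hla_class = HlaClass(hla_class)
        self._records: dict[str, LigandRecord] = {}
        self.multiplicity: Counter[str] = Counter()
        if records is not None:
            for rec in records:
                self.add(rec)

    @classmethod
    def from_sequences(cls, sequences: Iterable[str],
                       hla_class: HlaClass = HlaClass.I,
                       **record_kwargs) -> "LigandSet":
        ls = cls(hla_class)
        for seq in sequences:
            ls.add(LigandRecord(peptide=seq, hla_class=ls.hla_class, **record_kwargs))
        return ls

    def add(self, record: LigandRecord) -> None:
        if record.hla_class != self.hla_class:
            raise FormatError(
                f"record of class {record.hla_class.value} added to a "
                f"class {self.hla_class.value} set"
            )
        self.multiplicity[record.peptide] += 1
        self._records.setdefault(record.peptide, record)

    def sequences(self) -> list[str]:
        return list(self._records)

    def sequence_set(self) -> frozenset[str]:
        return frozenset(self._records)

    def records(self) -> list[LigandRecord]:
        return list(self._records.values())

    def get(self, sequence: str) -> LigandRecord | None:
        return self._records.get(sequence)

    def restricted_to(self, keep: Iterable[str]) -> "LigandSet":
        """New set with only the given sequences, preserving order and metadata."""
        keep_set = set(keep)
        out = LigandSet(self.hla_class)
        for seq, rec in self._records.items():
            if seq in keep_set:
                out.add(rec)
                out.multiplicity[seq] = self.multiplicity[seq]
        return out

    def __len__(self) -> int:
        return len(self._records)

    def __contains__(self, sequence: str) -> bool:
        return sequence in self._records

    def __iter__(self) -> Iterator[str]:
        return iter(self._records)

    def __repr__(self) -> str:
        return f"LigandSet(class={self.hla_class.value}, n={len(self)})"


def _reference_sequences(reference) -> list[str]:
    if isinstance(reference, LigandSet):
        return reference.sequences()
    return [validate_peptide(s) for s in reference]


def subtract(query: LigandSet, reference, mode: SubtractMode | str = SubtractMode.EXACT
             ) -> LigandSet:
    """Remove peptides of ``query`` matched by ``reference`` under ``mode``.

    ``reference`` may be a :class:`LigandSet` or any iterable of sequences;
    an empty reference returns the query unchanged. The output is always a
    subset of the input.
    """
    try:
        mode = SubtractMode(mode)
    except ValueError as exc:
        raise ValueError(f"unknown subtraction mode: {mode!r}") from exc
    refs = _reference_sequences(reference)
    if not refs:
        return query.restricted_to(query.sequences())
    if mode is SubtractMode.EXACT:
        ref_set = set(refs)
        keep = [s for s in query if s not in ref_set]
    elif mode is SubtractMode.QUERY_WITHIN_REFERENCE:
        keep = [s for s in query if not any(s in r for r in refs)]
    else:  # REFERENCE_WITHIN_QUERY
        keep = [s for s in query if not any(r in s for r in refs)]
    return query.restricted_to(keep)


@dataclass
class PatientHLA:
    """A patient's HLA class I typing (two-digit allele group names, e.g. ``A*02``)."""

    patient_id: str
    class_i_alleles: tuple[str, ...]

    def __post_init__(self) -> None:
        alleles = tuple(normalize_allele(a) for a in self.class_i_alleles)
        if not 1 <= len(alleles) <= 4:
            raise FormatError(
                f"patient {self.patient_id}: expected 1-4 class I alleles, "
                f"got {len(alleles)}"
            )
        self.class_i_alleles = alleles


def normalize_allele(name: str) -> str:
    """Normalize an allele group name to the ``A*02`` form.

    Accepts ``A*02``, ``A02``, ``HLA-A*02``, ``a*2`` and similar variants.
    """
    n = name.strip().upper().replace("HLA-", "")
    if "*" in n:
        locus, _, group = n.partition("*")
    else:
        locus, group = n[0], n[1:]
    locus = locus.strip()
    group = group.strip()
    if not locus or not group or not group.isdigit():
        raise FormatError(f"cannot parse HLA allele name: {name!r}")
    return f"{locus}*{int(group):02d}"


# ---------------------------------------------------------------------------
# Delimited-text I/O
# ---------------------------------------------------------------------------

_DEFAULT_COLUMNS = {"sequence": "sequence", "patient": "patient", "tissue": "tissue"}


def sniff_delimiter(header_line: str) -> str:
    """Tab wins over comma when both occur (TSV exports often contain commas)."""
    return "\t" if "\t" in header_line else ","


def read_ligand_table(path: str | Path, hla_class: HlaClass | str,
                      columns: Mapping[str, str] | None = None,
                      delimiter: str | None = None) -> tuple[LigandSet, IngestLog]:
    """Read a peptide identification table into a deduplicated :class:`LigandSet`.

    The file must have columns for the peptide sequence, patient and tissue
    (header names configurable via ``columns``; a ``source_proteins`` column,
    ``;``-separated, is used when present). Rows whose peptide length falls
    outside the class-specific range are dropped and counted; rows with
    non-alphabet characters are rejected and logged, neither aborts the read.
    """
    hla_class = HlaClass(hla_class)
    cols = dict(_DEFAULT_COLUMNS)
    if columns:
        cols.update(columns)
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise FormatError(f"{path}: empty file")
    first_line = text.splitlines()[0]
    delim = delimiter or sniff_delimiter(first_line)
    reader = csv.DictReader(io.StringIO(text), delimiter=delim)
    header = reader.fieldnames or []
    for role in ("sequence", "patient", "tissue"):
        if cols[role] not in header:
            raise FormatError(
                f"{path}: missing required column {cols[role]!r} (role: {role})"
            )
    lo, hi = hla_class.length_range
    ls = LigandSet(hla_class)
    log = IngestLog()
    for i, row in enumerate(reader, start=2):
        log.n_rows += 1
        raw_seq = (row.get(cols["sequence"]) or "").strip()
        try:
            seq = validate_peptide(raw_seq)
        except AlphabetError:
            log.n_alphabet_rejected += 1
            log.rejected_rows.append((i, raw_seq))
            continue
        if not lo <= len(seq) <= hi:
            log.n_length_dropped += 1
            continue
        proteins = tuple(
            p for p in (row.get("source_proteins") or "").split(";") if p
        )
        tissue = Tissue.parse(row.get(cols["tissue"]) or "tumor")
        if seq in ls:
            log.n_duplicates += 1
        ls.add(LigandRecord(
            peptide=seq,
            patient_id=(row.get(cols["patient"]) or "").strip(),
            tissue=tissue,
            hla_class=hla_class,
            source_proteins=proteins,
        ))
        log.n_kept = len(ls)
    return ls, log


def write_ligand_table(ligands: LigandSet, path: str | Path,
                       provenance: str = "", delimiter: str = "\t") -> None:
    """Serialize a ligand set as delimited text with a provenance column."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        writer.writerow(["sequence", "patient", "tissue", "hla_class",
                         "source_proteins", "multiplicity", "provenance"])
        for rec in ligands.records():
            writer.writerow([
                rec.peptide, rec.patient_id, rec.tissue.value,
                rec.hla_class.value, ";".join(rec.source_proteins),
                ligands.multiplicity[rec.peptide], provenance,
            ])
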