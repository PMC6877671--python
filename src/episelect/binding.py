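"""Matrix-based HLA binding scoring and binder classification.

The score model is the classical additive position-specific scoring matrix
(PSSM): a peptide of length L is scored against an allele- and
length-specific matrix by summing one integer weight per position; the
*relative score* expresses that sum as a percentage of the maximal allelic
score (the sum of per-position maxima). A peptide is called a binder for a
patient when it exceeds a relative-score threshold on at least one of the
patient's alleles, optionally combined with an external IC50 affinity
predictor (lower IC50 = stronger binding, conventional cutoff 500 nM).

The affinity predictor is a pluggable contract — any callable
``(peptide, allele) -> float | None`` — because published predictions come
from external tools whose versions vary; a deterministic table-lookup
implementation is bundled for tests and offline use.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Optional

from ._rounding import round_half_up
from .core import AMINO_ACIDS, PatientHLA, normalize_allele, validate_peptide
from .errors import ConfigurationError, FormatError, ScoringError

#: Contract for external affinity predictors: IC50 in nM, or None if the
#: peptide/allele pair is unsupported.
AffinityPredictor = Callable[[str, str], Optional[float]]


@dataclass(frozen=True)
class AlleleScoreMatrix:
    """Per-allele, per-length PSSM with integer weights.

    ``weights`` maps 1-based position -> residue -> weight; undefined
    (position, residue) pairs score 0. ``max_score`` is the sum over
    positions of the per-position maximum weight.
    """

    allele: str
    length: int
    weights: Mapping[int, Mapping[str, int]]

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ConfigurationError(f"matrix length {self.length} < 1")
        for pos in range(1, self.length + 1):
            if not self.weights.get(pos):
                raise ConfigurationError(
                    f"matrix {self.allele}/{self.length}: position {pos} has no weights"
                )
        if self.max_score <= 0:
            raise ConfigurationError(
                f"matrix {self.allele}/{self.length}: max_score must be positive"
            )

    @property
    def max_score(self) -> int:
        return sum(max(col.values()) for col in
                   (self.weights[p] for p in range(1, self.length + 1)))


def score_peptide(peptide: str, matrix: AlleleScoreMatrix) -> int:
    """Raw additive score: sum of per-position weights; missing entries are 0."""
    pep = validate_peptide(peptide)
    if len(pep) != matrix.length:
        raise ScoringError(
            f"peptide length {len(pep)} does not match matrix length {matrix.length}"
        )
    return sum(matrix.weights[i + 1].get(res, 0) for i, res in enumerate(pep))


def relative_score(peptide: str, matrix: AlleleScoreMatrix) -> float:
    """Percent of the maximal allelic score, rounded half-up to one decimal.

    Threshold comparisons elsewhere use the unrounded ratio
    (:func:`relative_score_raw`); rounding here is a reporting convention.
    """
    return round_half_up(relative_score_raw(peptide, matrix), 1)


def relative_score_raw(peptide: str, matrix: AlleleScoreMatrix) -> float:
    return 100.0 * score_peptide(peptide, matrix) / matrix.max_score


@dataclass
class BindingAssessment:
    """Result of evaluating one peptide on one allele."""

    peptide: str
    allele: str
    raw_score: int | None = None
    relative_score: float | None = None  # rounded, 0-100 scale
    relative_score_raw: float | None = None
    predicted_ic50: float | None = None
    is_binder: bool = False


@dataclass
class BinderCall:
    """Per-allele assessments plus the patient-level verdict.

    ``overall`` is None when no allele could evaluate the peptide at all
    (no matrix of matching length and no predictor support) — an
    *unevaluable* outcome, deliberately distinct from a confident non-binder.
    """

    peptide: str
    per_allele: dict[str, BindingAssessment] = field(default_factory=dict)
    overall: bool | None = None

    @property
    def evaluable(self) -> bool:
        return self.overall is not None


class MatrixRegistry:
    """Lookup of score matrices by (allele, peptide length)."""

    def __init__(self, matrices: Iterable[AlleleScoreMatrix] = ()):
        self._by_key: dict[tuple[str, int], AlleleScoreMatrix] = {}
        for m in matrices:
            self.add(m)

    def add(self, matrix: AlleleScoreMatrix) -> None:
        key = (normalize_allele(matrix.allele), matrix.length)
        self._by_key[key] = matrix

    def get(self, allele: str, length: int) -> AlleleScoreMatrix | None:
        return self._by_key.get((normalize_allele(allele), length))

    def lengths_for(self, alleles: Iterable[str]) -> list[int]:
        names = {normalize_allele(a) for a in alleles}
        return sorted({ln for (al, ln) in self._by_key if al in names})

    def alleles(self) -> list[str]:
        return sorted({al for (al, _) in self._by_key})

    def __len__(self) -> int:
        return len(self._by_key)


class TableLookupPredictor:
    """Deterministic affinity predictor backed by a (peptide, allele) -> nM table."""

    def __init__(self, table: Mapping[tuple[str, str], float] | None = None):
        self._table: dict[tuple[str, str], float] = {}
        if table:
            for (pep, allele), ic50 in table.items():
                self._table[(validate_peptide(pep), normalize_allele(allele))] = float(ic50)

    def __call__(self, peptide: str, allele: str) -> float | None:
        return self._table.get((validate_peptide(peptide), normalize_allele(allele)))

    @classmethod
    def from_file(cls, path: str | Path, delimiter: str | None = None
                  ) -> "TableLookupPredictor":
        """Load from delimited text with columns peptide, allele, ic50_nm."""
        text = Path(path).read_text()
        delim = delimiter or ("\t" if "\t" in text.splitlines()[0] else ",")
        reader = csv.DictReader(io.StringIO(text), delimiter=delim)
        required = {"peptide", "allele", "ic50_nm"}
        if not required <= set(reader.fieldnames or []):
            raise FormatError(
                f"{path}: predictor table needs columns {sorted(required)}"
            )
        table = {(r["peptide"], r["allele"]): float(r["ic50_nm"]) for r in reader}
        return cls(table)


def classify_binder(peptide: str, patient: PatientHLA, matrices: MatrixRegistry,
                    predictor: AffinityPredictor | None = None,
                    syfpeithi_threshold: float = 50.0,
                    ic50_threshold: float = 500.0,
                    rule: str = "or") -> BinderCall:
    """Call a peptide binder/non-binder against all of a patient's alleles.

    Per allele: matrix pass = relative score strictly above
    ``syfpeithi_threshold``; predictor pass = IC50 strictly below
    ``ic50_threshold``. ``rule`` combines the two within an allele:
    ``"or"`` (default; either evidence suffices) or ``"and"`` (both
    required, each unavailable criterion counts as failed). The peptide is
    an overall binder iff at least one allele is.
    """
    if rule not in ("or", "and"):
        raise ConfigurationError(f"unknown combination rule: {rule!r}")
    pep = validate_peptide(peptide)
    call = BinderCall(peptide=pep)
    any_evaluable = False
    for allele in patient.class_i_alleles:
        assessment = BindingAssessment(peptide=pep, allele=allele)
        matrix = matrices.get(allele, len(pep))
        matrix_pass = None
        if matrix is not None:
            assessment.raw_score = score_peptide(pep, matrix)
            assessment.relative_score_raw = relative_score_raw(pep, matrix)
            assessment.relative_score = round_half_up(assessment.relative_score_raw, 1)
            matrix_pass = assessment.relative_score_raw > syfpeithi_threshold
        ic50_pass = None
        if predictor is not None:
            ic50 = predictor(pep, allele)
            if ic50 is not None:
                assessment.predicted_ic50 = ic50
                ic50_pass = ic50 < ic50_threshold
        votes = [v for v in (matrix_pass, ic50_pass) if v is not None]
        if votes:
            any_evaluable = True
            assessment.is_binder = (any(votes) if rule == "or"
                                    else all(votes) and len(votes) == 2)
        call.per_allele[allele] = assessment
    if any_evaluable:
        call.overall = any(a.is_binder for a in call.per_allele.values())
    return call


# ---------------------------------------------------------------------------
# Matrix file I/O: one file per allele/length; header row of residues,
# one row per position, integer weights. An optional leading comment line
# "# allele=A*02 length=9" carries metadata; otherwise pass allele explicitly.
# ---------------------------------------------------------------------------

def read_matrix(path: str | Path, allele: str | None = None,
                delimiter: str | None = None) -> AlleleScoreMatrix:
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    meta: dict[str, str] = {}
    if lines and lines[0].startswith("#"):
        for token in lines.pop(0).lstrip("#").split():
            if "=" in token:
                k, _, v = token.partition("=")
                meta[k] = v
    allele = allele or meta.get("allele")
    if allele is None:
        raise FormatError(f"{path}: allele not given and no '# allele=' header")
    delim = delimiter or sniff_matrix_delim(lines[0])
    rows = [ln.split(delim) for ln in lines]
    header = [c.strip() for c in rows[0]]
    residues = header[1:] if header and header[0].lower() in ("pos", "position", "") \
        else header
    offset = len(header) - len(residues)
    for res in residues:
        if res not in AMINO_ACIDS:
            raise FormatError(f"{path}: unexpected residue column {res!r}")
    weights: dict[int, dict[str, int]] = {}
    for pos, row in enumerate(rows[1:], start=1):
        cells = [c.strip() for c in row[offset:]]
        if len(cells) != len(residues):
            raise FormatError(f"{path}: row {pos} has {len(cells)} cells, "
                              f"expected {len(residues)}")
        weights[pos] = {res: int(c) for res, c in zip(residues, cells) if c != ""}
    return AlleleScoreMatrix(allele=normalize_allele(allele),
                             length=len(weights), weights=weights)


def sniff_matrix_delim(line: str) -> str:
    return "\t" if "\t" in line else ","


def write_matrix(matrix: AlleleScoreMatrix, path: str | Path,
                 delimiter: str = "\t") -> None:
    path = Path(path)
    residues = sorted({res for col in matrix.weights.values() for res in col})
    with path.open("w") as fh:
        fh.write(f"# allele={matrix.allele} length={matrix.length}\n")
        fh.write(delimiter.join(["pos", *residues]) + "\n")
        for pos in range(1, matrix.length + 1):
            col = matrix.weights[pos]
            fh.write(delimiter.join(
                [str(pos), *(str(col.get(res, 0)) for res in residues)]) + "\n")


def load_matrix_dir(directory: str | Path) -> MatrixRegistry:
    """Load every ``*.tsv``/``*.csv`` matrix file in a directory."""
    registry = MatrixRegistry()
    for path in sorted(Path(directory).glob("*.[tc]sv")):
        registry.add(read_matrix(path))
    return registry
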