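"""Expression-based curation metrics and candidate ranking.

Three criteria support the manual curation of tumor-exclusive candidate
peptides: tumor-over-normal expression of the source gene (log2 fold change
of CPM-normalized read counts), the frequency at which the peptide was
identified across a cohort of samples (nested length variants count for
class II), and a user-supplied tumor-association annotation. Variant- and
fusion-derived candidates are ranked first regardless of these scores, and
the final list is truncated to the per-patient testing capacity (6-9
peptides in practice).

The fold-change pseudocount defaults to 1 CPM; the ranking weights default
to equal. Both are configuration, not biology: the package never invents a
tumor-association judgement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import HlaClass, LigandSet, is_nested


def cpm_normalize(counts: Mapping[str, float] | pd.Series) -> pd.Series:
    """Counts-per-million: counts * 1e6 / library size."""
    s = pd.Series(counts, dtype=float)
    if (s < 0).any():
        raise ValueError("negative read counts")
    total = s.sum()
    if total <= 0:
        raise ValueError("zero library size")
    return s * 1e6 / total


def log2_fold_change(tumor_cpm, normal_cpm, pseudocount: float = 1.0):
    """log2((tumor + pc) / (normal + pc)); antisymmetric in its arguments."""
    t = np.asarray(tumor_cpm, dtype=float)
    n = np.asarray(normal_cpm, dtype=float)
    if (t < 0).any() or (n < 0).any():
        raise ValueError("negative CPM values")
    fc = np.log2((t + pseudocount) / (n + pseudocount))
    if np.isscalar(tumor_cpm) or np.ndim(tumor_cpm) == 0:
        return float(fc)
    if isinstance(tumor_cpm, pd.Series):
        return pd.Series(fc, index=tumor_cpm.index)
    return fc


@dataclass
class ExpressionProfile:
    """Per-gene tumor/normal counts, CPM and log2 fold change."""

    table: pd.DataFrame  # columns: tumor_counts, normal_counts, tumor_cpm, normal_cpm, log2_fc

    @classmethod
    def from_counts(cls, tumor_counts: Mapping[str, float],
                    normal_counts: Mapping[str, float],
                    pseudocount: float = 1.0) -> "ExpressionProfile":
        genes = sorted(set(tumor_counts) | set(normal_counts))
        t = pd.Series({g: float(tumor_counts.get(g, 0)) for g in genes})
        n = pd.Series({g: float(normal_counts.get(g, 0)) for g in genes})
        t_cpm = cpm_normalize(t)
        n_cpm = cpm_normalize(n)
        fc = log2_fold_change(t_cpm, n_cpm, pseudocount)
        return cls(pd.DataFrame({
            "tumor_counts": t, "normal_counts": n,
            "tumor_cpm": t_cpm, "normal_cpm": n_cpm, "log2_fc": fc,
        }))

    def fc_of(self, gene: str) -> float | None:
        if gene in self.table.index:
            return float(self.table.loc[gene, "log2_fc"])
        return None


def cohort_frequency(peptide: str, cohort: Sequence[LigandSet],
                     hla_class: HlaClass | str) -> float:
    """Fraction of cohort samples presenting the peptide.

    Class I counts exact sequence matches; class II counts any nested
    length variant as a hit."""
    if not cohort:
        raise ValueError("empty cohort")
    hla_class = HlaClass(hla_class)
    hits = 0
    for sample in cohort:
        if hla_class is HlaClass.I:
            if peptide in sample:
                hits += 1
        else:
            if any(is_nested(peptide, other) for other in sample):
                hits += 1
    return hits / len(cohort)


@dataclass
class CurationRecord:
    """One candidate peptide with its curation evidence."""

    peptide: str
    hla_class: HlaClass = HlaClass.I
    source_gene: str = ""
    fc: float = 0.0
    cohort_frequency: float = 0.0
    tumor_association: float = 0.0   # user-supplied annotation (0/1 or a weight)
    from_variant: bool = False       # mutated or fusion-derived
    best_relative_score: float | None = None
    rank: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.cohort_frequency <= 1.0:
            raise ValueError("cohort_frequency outside [0, 1]")


@dataclass
class RankingWeights:
    fc: float = 1.0
    cohort_frequency: float = 1.0
    tumor_association: float = 1.0


def rank_candidates(records: Sequence[CurationRecord],
                    weights: RankingWeights | None = None,
                    cap: int = 9) -> list[CurationRecord]:
    """Deterministic ranking: variant/fusion-derived first, then by weighted
    score of (FC, cohort frequency, tumor association), ties broken
    lexicographically by sequence; the list is truncated at ``cap``.

    A cap outside 1..len(records) is clamped with a warning. Input records
    are not mutated; returned copies carry 1-based ranks.
    """
    w = weights or RankingWeights()

    def score(r: CurationRecord) -> float:
        return (w.fc * r.fc + w.cohort_frequency * r.cohort_frequency
                + w.tumor_association * r.tumor_association)

    ordered = sorted(records,
                     key=lambda r: (not r.from_variant, -score(r), r.peptide))
    n = len(ordered)
    if n and not 1 <= cap <= n:
        clamped = min(max(cap, 1), n)
        warnings.warn(f"cap {cap} outside 1..{n}; clamped to {clamped}",
                      stacklevel=2)
        cap = clamped
    out = []
    for i, rec in enumerate(ordered[:cap], start=1):
        from dataclasses import replace
        out.append(replace(rec, rank=i))
    return out
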