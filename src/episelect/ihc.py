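"""Immunohistochemistry scoring arithmetic and group comparison.

Covers the quantification conventions used for stained FFPE tumor sections:
the immunoreactive score (IRS; binned percent-positive 0-4 times staining
intensity 0-3, range 0-12), mean positive-cell counts over five high-power
fields (HPF, 200x magnification), percent positive tumor cells, hot-spot
region selection (top-k regions by count), and the Mann-Whitney U test for
comparing two patient groups. Counts are counts here — whether they came
from automated or manual enumeration is input metadata, not a different
code path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import FormatError

SIGNIFICANCE_LEVEL = 0.05


class PatientGroup(str, Enum):
    RFA_PLUS_SURGERY = "RFA_plus_surgery"
    SURGERY_ONLY = "surgery_only"


class Compartment(str, Enum):
    TUMOR_CENTER = "tumor_center"
    INVASIVE_MARGIN = "invasive_margin"


@dataclass
class IhcCountRecord:
    """Per-patient, per-marker IHC quantification in one compartment."""

    patient_id: str
    group: PatientGroup
    marker: str
    compartment: Compartment = Compartment.TUMOR_CENTER
    hpf_counts: tuple[float, ...] = ()       # positive cells per HPF
    region_counts: tuple[float, ...] = ()    # per-region counts (hot-spot method)
    region_area_mm2: float = 0.2
    percent_positive: float | None = None    # e.g. HLA-DR: % positive tumor cells
    positivity_fraction: float | None = None  # IRS markers: % positive cells
    intensity: int | None = None             # IRS markers: 0-3


@dataclass(frozen=True)
class IrsScore:
    """Immunoreactive score: positivity bin (0-4) x intensity (0-3)."""

    positivity_bin: int
    intensity: int

    @property
    def irs(self) -> int:
        return self.positivity_bin * self.intensity


def positivity_bin(percent_positive: float) -> int:
    """Bin percent-positive cells: 0 -> 0, (0,10] -> 1, (10,50] -> 2,
    (50,80] -> 3, >80 -> 4. Fractional percentages fall into the bin whose
    printed integer range contains their ceiling."""
    p = float(percent_positive)
    if not 0.0 <= p <= 100.0:
        raise ValueError(f"percent positive {p} outside [0, 100]")
    if p == 0:
        return 0
    if p <= 10:
        return 1
    if p <= 50:
        return 2
    if p <= 80:
        return 3
    return 4


def irs(percent_positive: float, intensity: int) -> IrsScore:
    """Immunoreactive score of a sample; range 0-12."""
    if intensity not in (0, 1, 2, 3):
        raise ValueError(f"staining intensity {intensity} not in 0..3")
    return IrsScore(positivity_bin=positivity_bin(percent_positive),
                    intensity=int(intensity))


def mean_per_hpf(counts: Sequence[float], expected_fields: int = 5) -> float:
    """Arithmetic mean of positive-cell counts over the high-power fields."""
    if len(counts) != expected_fields:
        raise FormatError(
            f"expected {expected_fields} HPF counts, got {len(counts)}")
    return float(np.mean(counts))


def hotspot_select(region_counts: Sequence[float], k: int = 3) -> list[float]:
    """The k regions with the highest counts, descending; ties keep input
    order (stable sort). Fewer than k regions returns all with a warning."""
    counts = list(region_counts)
    if len(counts) < k:
        warnings.warn(f"only {len(counts)} regions for hot-spot selection "
                      f"(k={k}); returning all", stacklevel=2)
        k = len(counts)
    order = sorted(range(len(counts)), key=lambda i: (-counts[i], i))
    return [counts[i] for i in order[:k]]


def compare_groups(values_a: Sequence[float], values_b: Sequence[float],
                   exact_max_n: int = 8) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Uses the exact null distribution when both groups have at most
    ``exact_max_n`` observations (and no ties force an approximation),
    the normal approximation otherwise. Returns (U of the first group,
    two-sided p). Significance is conventionally judged at p < 0.05.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    method = "exact" if (a.size <= exact_max_n and b.size <= exact_max_n) \
        else "asymptotic"
    try:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    except ValueError:
        # exact method refuses ties in some scipy versions; fall back
        res = stats.mannwhitneyu(a, b, alternative="two-sided",
                                 method="asymptotic")
    return float(res.statistic), float(res.pvalue)
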