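# Methods

This note documents the models, conventions and design choices behind
`episelect`, in the spirit of a statistical-software methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Ligandome model

An HLA ligandome is modeled as a deduplicated set of peptide sequences over
the 20-letter amino-acid alphabet, each carrying patient, tissue and HLA
class provenance. Identity is the uppercased sequence string; isoleucine and
leucine are kept distinct even though tandem MS cannot separate them,
because reproducible set algebra on published identification lists matters
more here than mass-level ambiguity. Deduplication keeps the first-seen
record's metadata and retains a multiplicity count. Length ranges follow
standard immunopeptidomics search settings — 8–12 residues for HLA class I,
9–25 for class II — and rows outside the range are dropped (and counted) at
ingest rather than rejected fatally, since MS exports routinely contain
stray identifications.

Subtraction has three modes: `exact` (sequence identity), and two
substring-containment modes that encode the *length variant* relation of
class II ligands, whose open binding groove produces nested sets of peptides
sharing a core. Containment is contiguous substring matching; no core-epitope
alignment is attempted, so a class II variant shifted by a gap would not be
caught. All three modes are property-tested against a quadratic brute-force
oracle.

## Binding model

Binding is scored by additive position-specific scoring matrices: integer
weight per (position, residue), undefined pairs scoring 0, and the
*relative score* defined as 100 × score / max-score, where max-score sums
the per-position maxima. Relative scores are invariant under positive
scaling of the weights. Reported percentages round half-up to one decimal;
all threshold comparisons use unrounded values, and all printed thresholds
are strict inequalities (>50%, >60%, <500 nM, >25 reads, >10 split reads,
>0.8 probability), matching how they are conventionally quoted.

External affinity predictors are reduced to a contract — a deterministic
callable `(peptide, allele) → IC50 nM or unsupported` — with a bundled
table-lookup implementation. Within an allele, matrix and predictor evidence
combine by OR by default (either suffices), switchable to AND; across
alleles a peptide is a binder if any allele accepts it. A peptide no allele
can evaluate is *unevaluable*, a distinct outcome from a confident
non-binder. Allele names are normalized to two-digit group form (`A*02`).

## Selection cascades

Both cascades are ordered lists of named, individually disableable filters,
because the source workflows differ between patients (e.g. the autologous
liver subtraction is skipped when no autologous tissue exists). The default
class I order is: binder classification; motif confirmation (matrix relative
score >50% on ≥1 patient allele; a stricter predictor-agreement mode is
selectable and recorded in the trace metadata); exact subtraction of
autologous + cohort non-malignant liver, then non-malignant colon, then a
multi-tissue benign class I compendium; removal of peptides nested inside
any class II ligand; and finally relative score >60%. The class II order is
the four exact subtractions followed by removal of candidates containing a
benign class I ligand as a substring.

Two structural facts are property-tested: retained sets are nested along the
trace (counts monotone non-increasing), and the exact-subtraction block is
order-independent in membership — permuting those steps changes only the
intermediate counts, never the final set. Final candidates are ordered by
best relative score descending, then lexicographically, so reports are
deterministic.

## Neoepitope prediction

Inputs are protein-level changes (substitution, in-frame insertion/deletion,
frameshift with an explicitly supplied alternate tail); no transcript models
or codon translation are performed. Variant filters: non-synonymous
consequence, tumor depth strictly >25 reads (interpreted as total read depth
at the locus), zero alt-supporting reads in the matched normal
("undetectable"), and a single-locus transcript. Fusion filters: >10 split
reads and caller probability >0.8 on the 0–1 scale — the probability
threshold is sometimes quoted with a stray percent sign; it is treated as a
fraction and is configurable. Driver/relevance curation is externalized to a
user-supplied gene whitelist; the package hard-codes no cancer-gene list.

Window scanning enumerates *every* window containing a mutated residue, at
every length for which the patient has a matrix — a superset of any fixed
flank choice, which errs toward sensitivity. The 15-mer extension
distributes flanks as evenly as possible with the odd residue to the
C-terminal side; clipping at a protein end shifts the deficit to the other
side, and proteins shorter than 15 residues are unextendable by definition.
The wildtype counterpart is emitted for substitutions (where positions
align); indel and fusion products have no aligned 15-mer counterpart.

## Curation metrics

CPM is plain counts × 10⁶ / library size; the log2 fold change uses a
pseudocount (default 1.0 CPM, configurable) to stay defined at zero
expression — the value is a filtering criterion, not a test statistic, so no
dispersion modeling is warranted. Cohort frequency counts exact matches for
class I and any nested length variant for class II. Ranking places
variant/fusion-derived candidates first unconditionally, then sorts by an
equally-weighted sum of fold change, cohort frequency and the user-supplied
tumor-association annotation (the package never invents that biological
judgment); ties break lexicographically and the list is capped (default 9,
reflecting per-patient assay capacity of 6–9 peptides).

## ICS response calling

A marker is positive when its percentage is ≥2-fold the matched DMSO
control percentage *and* its event count exceeds the control count by ≥20
cells; a stimulus is positive when ≥2 of the 5 markers are. Two conventions
deserve note. First, "2-fold above" is implemented inclusively (≥2×);
the wording is ambiguous and the parameter is exposed. Second, the excess
criterion subtracts raw gated event counts, not percentages, deliberately
leaving acquisition-size differences uncorrected — the criterion is about
having enough actual cells to believe.

Longitudinally, a stimulus is *absent* (never positive), *induced*
(pre-treatment negative, any post positive) or *pre-existing* (pre
positive). "Enhanced" has no quantitative published definition; the package
defines it as maximum post-treatment magnitude ≥2× the pre-treatment
magnitude, where magnitude is the summed background-subtracted percentage
over positive markers. The fold is a parameter and is flagged in report
metadata. Peptide pools are treated as single stimuli; deconvolution is out
of scope.

## IHC scoring

The immunoreactive score bins percent-positive cells (0; 1–10; 11–50;
51–80; >80 → 0–4) and multiplies by staining intensity (0–3), range 0–12.
Bin edges are inclusive as printed; fractional percentages in (0, 10] map to
bin 1. Counts are treated identically whether they came from automated or
manual enumeration — origin is metadata. Per-HPF means average exactly five
high-power fields by default (configurable); hot-spot selection takes the
top-k regions by count with ties resolved by input order, which the tests
verify is sum-maximal among all size-k subsets. Group comparisons use the
two-sided Mann-Whitney U test via scipy, with the exact null distribution
when both groups have ≤8 observations and the normal approximation
otherwise.

## Synthetic data

The generators emulate the *structure* of the real inputs, not their
biology: tumor ligandomes are unions of planted tumor-exclusive strong
binders (matching all anchor residues of one patient allele, hence relative
score 100%), weak tumor-exclusive peptides (anchor residues avoided, scores
well below 50%), and shared peptides distributed across the benign reference
roles; nested class I/class II pairs and class-II-containing-class-I
peptides are planted for the cross-class steps. Default sizes: ~500 class I
tumor peptides with 20 planted exclusives, 9-mer class I / 15-mer class II
peptides, two alleles with anchors at position 2 and the C-terminus
(anchor weight 12 over background 1, making anchor-matching peptides score
100% and anchor-avoiding ones ~23%).

ICS panels draw control percentages from a 0.05–0.15% background band over
subsets of 15,000–30,000 gated events; planted positive markers sit a fixed
1.0 percentage point above their control, which guarantees both calling
criteria across the whole band and makes magnitude ratios equal the planted
scale (3× for enhanced, 1.1× for stable) up to count rounding. The spec
validator rejects parameterizations that could not produce their labels.
IHC counts are negative binomial (mean 40, size 8 — overdispersed as real
per-field counts are) for groups of 8 and 7 patients with five fields each.

All generators are bit-reproducible: each draws from its own stream derived
from the scenario seed by fixed-spawn-key sub-seeding, so adding a generator
never perturbs the others.

What passing tests do **not** show: recovery on real data, where benign
compendia are incomplete, binding motifs overlap, length variants are noisy
and identification itself has an FDR. The planted scenarios verify the
*machinery* — filter semantics, order-invariance, threshold boundaries —
not field performance.

## Determinism and numerics

Reports are byte-identical across reruns for a fixed config: orderings are
fixed everywhere, percentages round half-up to one decimal, means to the
nearest integer (half-up), and comparisons always precede rounding.
Degenerate inputs have defined behavior: empty tumor sets yield all-zero
traces, empty references are identity subtractions, a missing (as opposed to
empty) reference raises a configuration error naming the sub-set, zero
library sizes and empty groups raise value errors.

## Known limitations

Substring semantics for nesting (no core alignment); protein-level variants
only; no FDR or spectral processing; no survival analysis; table-lookup
affinity prediction only (real predictors plug in via the contract); the
per-step counts of a published example funnel depend on proprietary benign
compendia and are therefore documented as an accession-dependent integration
check, not a desk-reproducible test.

## Problem sizes

Test and acceptance runs use the default synthetic sizes above (≈500-peptide
tumor ligandomes, 10 seeds for planted-truth recovery, ≥50 random instances
per brute-force oracle comparison, 100 seeded replicates for the IHC type-I
check), chosen to exercise every code path at sizes where the brute-force
oracles remain exact and fast.
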