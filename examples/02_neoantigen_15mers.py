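"""From a somatic substitution to a 15-mer synthetic long peptide.

Applies a V->L substitution to a receptor fragment, scans every peptide
window spanning the mutated residue against the patient's allele matrices,
and extends the best predicted binder to a 15-mer with its wildtype
counterpart — the format used for T cell stimulation, covering both class I
and class II presentation.
"""

from episelect import (PatientHLA, ProteinChange, apply_protein_change,
                       extend_to_15mer, scan_mutated_windows)
from episelect.binding import AlleleScoreMatrix, MatrixRegistry
from episelect.core import AMINO_ACIDS

# A receptor fragment; the substitution V9L mimics a tumor-private missense
# variant landing inside a predicted binder.
wildtype = "TLPLPNLRVVRGTQVAAGSLLQRSTW"
change = ProteinChange(position=9, ref="V", alt="L")
mutated = apply_protein_change(wildtype, change)
print(f"wildtype: {wildtype}")
print(f"mutated:  {mutated}  (edit at position {change.position})")

# A leucine-anchored 9-mer motif (anchor positions 2 and the C-terminus),
# the classical layout of an HLA-A*02-like binding matrix.
weights = {pos: {res: 1 for res in AMINO_ACIDS} for pos in range(1, 10)}
weights[2] = {"L": 10, "M": 8}
weights[9] = {"L": 6, "V": 2, "I": 2}
registry = MatrixRegistry([AlleleScoreMatrix("A*02", 9, weights)])
patient = PatientHLA("PT01", ("A*02",))

windows = scan_mutated_windows(mutated, [change.position], patient, registry,
                               rel_threshold=60)
print(f"\n{len(windows)} mutation-spanning windows above threshold; best:")
best = windows[0]
print(f"  {best.sequence} at {best.span}, relative score "
      f"{best.best_relative_score:.1f}% on {best.allele}")

long_peptide = extend_to_15mer(best, mutated, wildtype)
print(f"\n15-mer:   {long_peptide.sequence}")
print(f"wildtype: {long_peptide.wildtype_counterpart}")
diff = sum(a != b for a, b in zip(long_peptide.sequence,
                                  long_peptide.wildtype_counterpart))
print(f"residues differing from wildtype: {diff} "
      "(the mutated position only)")
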