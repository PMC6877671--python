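"""Expression support and deterministic ranking of candidate peptides.

CPM-normalizes a small tumor/normal count table, computes log2 fold changes,
scores cohort identification frequency, and ranks candidates with
variant-derived peptides placed first and the list capped at the per-patient
testing capacity.
"""

from episelect import (CurationRecord, ExpressionProfile, HlaClass,
                       LigandSet, cohort_frequency, rank_candidates)

profile = ExpressionProfile.from_counts(
    tumor_counts={"CCND1": 900, "FN1": 400, "GAPDH": 5000, "ALB": 20},
    normal_counts={"CCND1": 120, "FN1": 150, "GAPDH": 5200, "ALB": 2600})
print("gene-level expression support (log2 tumor/normal fold change of CPM):")
print(profile.table[["tumor_cpm", "normal_cpm", "log2_fc"]].round(2))

cohort = [LigandSet.from_sequences(s, HlaClass.II) for s in (
    ["NPPSMVAAGSVVAAV"], ["PPSMVAAGSVV"], ["GAKLMNPQRW"], [])]
freq = cohort_frequency("NPPSMVAAGSVVAAV", cohort, HlaClass.II)
print(f"\ncohort frequency of NPPSMVAAGSVVAAV (nested variants count): {freq}")

records = [
    CurationRecord("NPPSMVAAGSVVAAV", HlaClass.II, source_gene="CCND1",
                   fc=profile.fc_of("CCND1"), cohort_frequency=freq,
                   tumor_association=1.0),
    CurationRecord("VSVYALKDTLTSRPA", HlaClass.II, source_gene="FN1",
                   fc=profile.fc_of("FN1"), cohort_frequency=0.25,
                   tumor_association=1.0),
    CurationRecord("TLPLPNLRLVRGTQV", HlaClass.II, source_gene="ERBB3",
                   from_variant=True),
    CurationRecord("AAAGSLLQR", HlaClass.I, source_gene="ALB",
                   fc=profile.fc_of("ALB"), cohort_frequency=0.0),
]
ranked = rank_candidates(records, cap=3)
print("\nranked shortlist (variant-derived first, then weighted evidence):")
for r in ranked:
    print(f"  {r.rank}. {r.peptide:16s} gene={r.source_gene:6s} "
          f"fc={r.fc:+.2f} freq={r.cohort_frequency:.2f} "
          f"variant={r.from_variant}")
# The mutated peptide leads regardless of expression evidence; the liver
# housekeeping-derived candidate (negative fold change) is cut by the cap.
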