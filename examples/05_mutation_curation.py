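"""Mutation notation parsing and dataset curation rules.

Shows the positive/negative selection criteria and the pathogenic allele
frequency bound that screens population variants.
"""
from rps19struct import (MutationRecord, estimate_pathogenic_maf,
                         parse_protein_mutation, select_negatives,
                         select_positives)

print("parsed:", parse_protein_mutation("Gly127Arg"),
      parse_protein_mutation("K38N"))

low, high = estimate_pathogenic_maf(5e-6, 7e-6, 0.25, inheritance="dominant")
print(f"pathogenic MAF bound: {low:.3g} - {high:.3g}")
print(f"neutral-variant threshold (one order above the upper bound): "
      f"{high * 10:.3g}")

candidates = [
    MutationRecord(127, "G", "R", patient_count=5),
    MutationRecord(62, "R", "W", clinvar_significance="Likely pathogenic"),
    MutationRecord(55, "T", "M", functional_evidence=True),
    MutationRecord(23, "K", "R", patient_count=1),        # single report
]
positives = select_positives(candidates)
print("kept as disease mutations:", [m.name for m in positives])

population = [
    MutationRecord(70, "A", "T", allele_frequency=1.2e-4),
    MutationRecord(30, "V", "I", allele_frequency=2.0e-6),  # too rare to call
    MutationRecord(145, "H", "Y", allele_frequency=3.0e-5),
]
negatives = select_negatives(population, maf_upper=high,
                             exclusion_list={"A70T"})      # known disease allele
print("kept as neutral variants:", [m.name for m in negatives])

# Disease status needs replication, curation or experiment; population
# variants count as neutral only when far too common to be pathogenic and
# never previously reported as disease mutations.
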