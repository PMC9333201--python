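# Default comparison ledger: the adjustments applied before counting
# diplotype/phenotype agreement between two call sets. Every entry carries a
# reason. Users may extend this file; it is data, not code.

# Alleles newly added to nomenclature after the comparator set was produced.
# Calls carrying them are mapped to a surrogate for comparison and the key
# is not counted as a mismatch on account of that allele.
ignored_alleles:
  CYP2C8:
    "*15": {surrogate: "*1", reason: "recently added to nomenclature; absent from comparator call set"}
    "*16": {surrogate: "*1", reason: "recently added to nomenclature; absent from comparator call set"}
    "*17": {surrogate: "*1", reason: "recently added to nomenclature; absent from comparator call set"}

# Cell-line trisomy: one chromosome carried in three copies duplicates one
# allele of the diplotype; the duplicated allele is dropped before comparison
# (e.g. a *2/*2/*4 call is treated as *2/*4).
sample_adjustments:
  - sample: NA18540
    genes: [CYP3A4, CYP3A5, UGT2B7, UGT2B15, UGT2B17]
    action: drop_duplicated_allele
    reason: "cell-line trisomy artifact, not natural pharmacogene variation"

# Legacy notation used by earlier publications for the same configuration.
notation_equivalences:
  CYP2D6:
    "(*36+)10": {canonical: "*36+*10", reason: "legacy tandem-hybrid notation"}

# Samples excluded from all comparisons.
excluded_samples:
  - sample: NA18973
    reason: "clerical sample swap; sequenced material was a different individual"
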