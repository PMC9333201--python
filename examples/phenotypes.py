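"""Activity scores and CPIC phenotypes for worked diplotypes."""

from pgxstar.phenotype import activity_score, predict_phenotype

for diplotype in ["*1/*1", "*1/*4", "*4/*5", "*1x2/*1", "*29/*106"]:
    result = predict_phenotype("CYP2D6", diplotype)
    score = activity_score("CYP2D6", diplotype)
    score_txt = f"{score:g}" if score is not None else "undefined"
    print(f"CYP2D6 {result.diplotype:10s} activity score {score_txt:9s} -> {result.phenotype}")

print(f"CYP2B6 *6/*8       (direct map)          -> {predict_phenotype('CYP2B6', '*6/*8').phenotype}")
# The score is the sum of the two alleles' activity values (1 normal, 0.5
# decreased, 0 none; an xN suffix multiplies by the copy count); 2 -> normal,
# 1 -> intermediate, 0 -> poor, >2.25 -> ultrarapid. Alleles with unknown
# function make the phenotype Indeterminate.
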