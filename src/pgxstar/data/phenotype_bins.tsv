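# Activity-score -> phenotype bins for the score-based genes.
# Interval convention: lo < score <= hi, except the first bin which is
# inclusive at lo. Bins tile [0, inf) exactly.
gene	lo	hi	phenotype
CYP2D6	0	0	Poor Metabolizer
CYP2D6	0	1	Intermediate Metabolizer
CYP2D6	1	2.25	Normal Metabolizer
CYP2D6	2.25	inf	Ultrarapid Metabolizer
CYP2C9	0	0.5	Poor Metabolizer
CYP2C9	0.5	1.5	Intermediate Metabolizer
CYP2C9	1.5	inf	Normal Metabolizer
DPYD	0	0.5	Poor Metabolizer
DPYD	0.5	1.5	Intermediate Metabolizer
DPYD	1.5	inf	Normal Metabolizer
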