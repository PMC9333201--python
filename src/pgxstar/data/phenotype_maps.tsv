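# Direct diplotype -> phenotype maps for the non-score genes of the CPIC
# nine-gene set. Diplotypes are stored in canonical order (see
# genotyper.render_diplotype); lookups normalize order first.
gene	diplotype	phenotype
CYP2B6	*1/*1	Normal Metabolizer
CYP2B6	*1/*6	Intermediate Metabolizer
CYP2B6	*1/*8	Intermediate Metabolizer
CYP2B6	*6/*6	Poor Metabolizer
CYP2B6	*6/*8	Poor Metabolizer
CYP2B6	*8/*8	Poor Metabolizer
CYP2C19	*1/*1	Normal Metabolizer
CYP2C19	*1/*2	Intermediate Metabolizer
CYP2C19	*2/*2	Poor Metabolizer
CYP2C19	*1/*17	Rapid Metabolizer
CYP2C19	*17/*17	Ultrarapid Metabolizer
CYP3A5	*1/*1	Normal Metabolizer
CYP3A5	*1/*3	Intermediate Metabolizer
CYP3A5	*3/*3	Poor Metabolizer
CYP3A5	*3/*6	Poor Metabolizer
CYP3A5	*6/*6	Poor Metabolizer
SLCO1B1	*1A/*1A	Normal Function
SLCO1B1	*1A/*1B	Normal Function
SLCO1B1	*1B/*1B	Increased Function
SLCO1B1	*1A/*5	Decreased Function
SLCO1B1	*5/*5	Poor Function
SLCO1B1	*5/*15	Poor Function
TPMT	*1/*1	Normal Metabolizer
TPMT	*1/*3C	Intermediate Metabolizer
TPMT	*3C/*3C	Poor Metabolizer
UGT1A1	*1/*1	Normal Metabolizer
UGT1A1	*1/*28	Intermediate Metabolizer
UGT1A1	*1/*80+*28	Intermediate Metabolizer
UGT1A1	*28/*28	Poor Metabolizer
UGT1A1	*80+*28/*80+*28	Poor Metabolizer
UGT1A1	*28/*80+*28	Poor Metabolizer
UGT1A1	*1/*36	Normal Metabolizer
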