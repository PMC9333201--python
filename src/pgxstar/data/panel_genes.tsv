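gene	chrom	function	probe_kb	set1_mean	set2_mean	design	cpic_pairs	cpic_a_pairs	fda_pairs
BCHE	chr3	Other	7.7	345.4	311.7	exon	2	0	1
CACNA1S	chr1	Target	16	177.3	151.6	exon	7	7	5
CFTR	chr7	Target	16.7	352	314.8	exon	2	1	1
CYB5R1	chr1	Metabolism	8.8	332.2	286.1	exon	1	0	1
CYB5R2	chr11	Metabolism	11.1	272.9	232.7	exon	1	0	1
CYB5R3	chr22	Metabolism	9.8	155.4	131.5	exon	1	0	1
CYB5R4	chr6	Metabolism	13.1	315.8	283	exon	1	0	1
CYP1A2	chr15	Metabolism	6.1	238.9	201.4	exon	0	0	0
CYP2A6	chr19	Metabolism	49.3	352.5	301.2	custom	0	0	0
CYP2B6	chr19	Metabolism	46.4	324	281.1	custom	4	1	1
CYP2C8	chr10	Metabolism	7.9	389.3	344	exon	3	0	0
CYP2C9	chr10	Metabolism	7.4	415	366.9	exon	24	11	12
CYP2C19	chr10	Metabolism	9.1	403.3	355	exon	21	8	16
CYP2D6	chr22	Metabolism	36.6	259.8	231.5	custom	73	16	59
CYP2E1	chr10	Metabolism	29.7	318.2	266.5	custom	0	0	0
CYP2J2	chr1	Metabolism	8	348.2	301.7	exon	0	0	0
CYP3A4	chr7	Metabolism	8.6	355.1	313.9	exon	1	0	0
CYP3A5	chr7	Metabolism	11	377.3	335.5	exon	4	1	0
CYP4F2	chr19	Metabolism	6.8	266	229.2	exon	3	1	0
DPYD	chr1	Excretion	14.1	328.1	293.2	exon	3	2	2
EGFR	chr7	Target	19.4	326.5	285.3	exon	0	0	0
F5	chr1	Other	16.5	383.6	336.8	exon	2	0	1
G6PD	chrX	Drug-induced disease	8.4	116.5	111.1	exon	34	3	23
GBA	chr1	Other	9	249	220.3	exon	1	1	1
GSTM1	chr1	Metabolism	11	146.8	108.5	custom	2	0	0
GSTP1	chr11	Metabolism	5.2	199.3	171.2	exon	4	0	0
GSTT1	chr22	Metabolism	11.6	134.8	89.9	custom	0	0	0
HLA-A	chr6	Toxicity	9.3	294.6	262	custom	3	1	1
HLA-B	chr6	Toxicity	9.4	318.4	271.7	custom	13	6	7
HLA-C	chr6	Toxicity	9.4	334.6	284.5	custom	2	0	0
HLA-DPB1	chr6	Toxicity	16.4	332.2	286.3	custom	1	0	0
HLA-DQA1	chr6	Toxicity	12	309.5	251	custom	1	0	1
HLA-DRB1	chr6	Toxicity	19.1	333.6	293.6	custom	2	0	1
HPRT1	chrX	Other	6.7	229.3	223.5	exon	1	0	1
IFNL3	chr19	Other	5.1	240.1	208.6	exon	2	2	1
LDLR	chr19	Target	11.9	235.8	200.4	exon	1	0	1
NAGS	chr17	Other	6.4	164.5	140.8	exon	2	0	1
NAT1	chr8	Metabolism/excretion	8	355.5	311	exon	0	0	0
NAT2	chr8	Metabolism/excretion	5.5	390.4	347.8	exon	7	1	5
NUDT15	chr13	Metabolism	6.2	362.3	320.4	exon	3	3	3
OTC	chrX	Other	6.4	271.2	263.2	exon	1	0	1
POLG	chr15	Other	11.9	242.4	206.4	exon	2	2	2
POR	chr7	Drug-induced disease	12.4	157.5	136.7	exon	0	0	0
PROC	chr2	Other	6.8	229.1	196.7	exon	1	0	1
PROS1	chr3	Other	10.1	323.1	287.9	exon	1	0	1
RYR1	chr19	Drug-induced disease	32.9	152.5	130.2	exon	7	7	5
SERPINC1	chr1	Other	6.5	337.7	299.8	exon	1	0	1
SLC15A2	chr3	Excretion	12.8	383	338.1	exon	0	0	0
SLC22A2	chr6	Excretion	51.5	325.6	286.4	custom	0	0	0
SLCO1B1	chr12	Absorption	8.8	328.4	300.4	exon	5	1	3
SLCO2B1	chr11	Absorption	15	268.5	231.5	exon	0	0	0
TPMT	chr6	Metabolism	7.8	268	235.3	exon	3	3	3
UGT1A1	chr2	Excretion	12.8	371.8	323.3	exon	7	2	6
UGT1A4	chr2	Excretion	7.7	350.5	302.6	exon	1	0	0
UGT2B7	chr4	Excretion	6.8	327	297.7	exon	0	0	0
UGT2B15	chr4	Excretion	30.6	331.7	299.3	custom	1	0	0
UGT2B17	chr4	Excretion	30.3	177.2	161.5	custom	0	0	0
VDR	chr12	Absorption	10.6	288	247	exon	2	0	0
VKORC1	chr16	Target	4.9	246.8	208	exon	1	1	1
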