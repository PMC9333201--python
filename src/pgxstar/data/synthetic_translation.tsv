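# Synthetic haplotype translation tables for the demonstration pipeline.
# Defining-variant coordinates are synthetic stand-ins EXCEPT the handful of
# literature-documented sites: CYP2A6*9 (19-41356379-A-C), UGT1A1*28/*36/*37
# (2-234668879 TA-repeat indels), CYP3A5*6 (7-99262835-C-T), UGT2B15*4
# (4-69536084-A-C, 4-69512847-T-G), CYP1A2*1L (15-75038220-G-A).
gene	allele	defining_variants	function	sv_tag
CYP2D6	*1		normal	none
CYP2D6	*2	22-42523500-C-T	normal	none
CYP2D6	*2x2	22-42523500-C-T	normal	dup
CYP2D6	*4	22-42524600-G-A	no_function	none
CYP2D6	*4x2	22-42524600-G-A	no_function	dup
CYP2D6	*5		no_function	del
CYP2D6	*6	22-42526100-T-A	no_function	none
CYP2D6	*9	22-42523200-AAG-A	decreased	none
CYP2D6	*10	22-42526500-C-T	decreased	none
CYP2D6	*17	22-42524100-C-A	decreased	none
CYP2D6	*29	22-42525200-G-A	decreased	none
CYP2D6	*41	22-42523800-G-A	decreased	none
CYP2D6	*106	22-42525900-A-G	unknown	none
CYP2D6	*36+*10	22-42526500-C-T	decreased	hyb:CYP2D7
CYP2D6	*36x2+*10	22-42526500-C-T	decreased	hyb:CYP2D7
CYP2D6	*68+*4	22-42524600-G-A	no_function	hyb:CYP2D7
CYP2E1	*1		normal	none
CYP2E1	*5	10-135340300-G-A	unassigned	none
CYP2E1	*7	10-135341500-G-T	unassigned	none
CYP2E1	*7x2	10-135341500-G-T	unassigned	dup
CYP2E1	*7x3	10-135341500-G-T	unassigned	mult
CYP2E1	*S1		unassigned	dup
GSTT1	*A		normal	none
GSTT1	*0		no_function	del
GSTM1	*A		normal	none
GSTM1	*B	1-110232500-G-C	normal	none
GSTM1	*Ax2		normal	dup
GSTM1	*0		no_function	del
UGT2B17	*1		normal	none
UGT2B17	*2		no_function	del
UGT2B15	*1		normal	none
UGT2B15	*2	4-69512000-G-T	decreased	none
UGT2B15	*4	4-69512847-T-G,4-69536084-A-C	decreased	none
UGT2B15	*S1		unassigned	del
CYP2A6	*1		normal	none
CYP2A6	*1x2		normal	dup
CYP2A6	*2	19-41351000-T-A	no_function	none
CYP2A6	*4		no_function	del
CYP2A6	*9	19-41356379-A-C	decreased	none
CYP2B6	*1		normal	none
CYP2B6	*6	19-41497900-G-T,19-41500200-A-G	decreased	none
CYP2B6	*8	19-41498500-G-A	no_function	none
CYP2B6	*29		no_function	hyb:CYP2B7
UGT1A1	*1		normal	none
UGT1A1	*6	2-234669500-G-A	decreased	none
UGT1A1	*28	2-234668879-C-CAT	decreased	none
UGT1A1	*36	2-234668879-CAT-C	increased	none
UGT1A1	*37	2-234668879-C-CATAT	decreased	none
UGT1A1	*80	2-234667800-C-T	decreased	none
UGT1A1	*80+*28	2-234667800-C-T,2-234668879-C-CAT	decreased	none
UGT1A1	*80+*37	2-234667800-C-T,2-234668879-C-CATAT	decreased	none
SLC22A2	*1		normal	none
SLC22A2	*2	6-160592000-C-T	unassigned	none
SLC22A2	*S1		unassigned	del
SLC22A2	*S2		unassigned	del
CYP1A2	*1A		normal	none
CYP1A2	*1F	15-75041000-C-A	unassigned	none
CYP1A2	*1L	15-75038220-G-A,15-75041000-C-A	unknown	none
CYP3A5	*1		normal	none
CYP3A5	*3	7-99270539-A-G	no_function	none
CYP3A5	*6	7-99262835-C-T	no_function	none
DPYD	Reference		normal	none
DPYD	c.85T>C (*9A)	1-97702000-A-G	normal	none
DPYD	c.1601G>A (*4)	1-97706000-C-T	normal	none
DPYD	c.1627A>G (*5)	1-97707000-T-C	normal	none
DPYD	c.2846A>T	1-97710000-T-A	decreased	none
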