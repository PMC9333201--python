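# Synthetic compact gene/pseudogene intervals (1-based inclusive) used by the
# demonstration translation tables and the depth simulator. Chromosome labels
# are real; interval sizes are kb-scale stand-ins for the true loci.
gene	chrom	gene_start	gene_end	pseudogene	pseudo_start	pseudo_end	control_eligible
CYP2D6	22	42522000	42527999	CYP2D7	42530000	42535999	0
CYP2E1	10	135339000	135344999				0
GSTT1	22	24376000	24381999				0
GSTM1	1	110230000	110235999				0
UGT2B17	4	69400000	69405999				0
UGT2B15	4	69506000	69537999				0
CYP2A6	19	41349000	41356999				0
CYP2B6	19	41497000	41502999	CYP2B7	41505000	41510999	0
UGT1A1	2	234666000	234681999				0
SLC22A2	6	160590000	160597999				0
CYP1A2	15	75038000	75047999				0
CYP3A5	7	99245000	99277999				0
DPYD	1	97700000	97715999				0
VDR	12	48235000	48242999				1
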