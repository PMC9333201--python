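# Per-allele activity values (CPIC convention: 1 normal, 0.5 decreased,
# 0 no function). An "xN" copy suffix multiplies the base value by N.
gene	allele	value
CYP2D6	*1	1
CYP2D6	*2	1
CYP2D6	*35	1
CYP2D6	*9	0.5
CYP2D6	*17	0.5
CYP2D6	*29	0.5
CYP2D6	*10	0.25
CYP2D6	*41	0.25
CYP2D6	*36+*10	0.25
CYP2D6	*36x2+*10	0.25
CYP2D6	*4	0
CYP2D6	*5	0
CYP2D6	*6	0
CYP2D6	*68+*4	0
CYP2C9	*1	1
CYP2C9	*2	0.5
CYP2C9	*8	0.5
CYP2C9	*11	0.5
CYP2C9	*61	0.5
CYP2C9	*3	0
CYP2C9	*5	0
CYP2C9	*6	0
DPYD	Reference	1
DPYD	c.85T>C (*9A)	1
DPYD	c.1601G>A (*4)	1
DPYD	c.1627A>G (*5)	1
DPYD	c.496A>G	1
DPYD	c.2846A>T	0.5
DPYD	c.1905+1G>A (*2A)	0
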