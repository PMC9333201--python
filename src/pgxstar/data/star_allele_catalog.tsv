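gene	reference_allele	alleles_reported	alleles_previously_not_reported
CYP1A2	*1A	*1A, *1F, *1L
CYP2A6	*1	*1, *1x2 (dup), *2, *4 (del), *7, *9, *15, *17, *18, *20, *21, *22, *23, *24, *25
CYP2B6	*1	*1, *2, *4, *5, *6, *9, *15, *17, *18, *20, *22, *23, *29 (hyb)
CYP2C8	*1	*1, *2, *3, *4, *15, *16, *17	*15, *16, *17
CYP2C9	*1	*1, *2, *3, *5, *6, *8, *9, *11, *61	*61
CYP2C19	*1	*1, *2, *3, *4, *6, *8, *13, *15, *17, *35, *39	*39
CYP2D6	*1	*1, *2, *2x2 (dup), *4, *4x2 (dup), *5 (del), *6, *9, *10, *14, *15, *17, *21, *29, *35, *36+*10 (hyb), *36x2+*10 (hyb), *40, *41, *45, *46, *68+*4 (hyb), *71, *106	*106
CYP2E1	*1	*1, *5, *7, *7x2 (dup), *7x3 (dup), *S1 (dup)
CYP3A4	*1	*1, *2, *3, *15, *16, *22
CYP3A5	*1	*1, *3, *6, *7
CYP4F2	*1	*1, *2, *3
DPYD	Reference	Reference, c.85T>C (*9A), c.496A>G, c.557A>G, c.1218G>A, c.1349C>T, c.1601G>A (*4), c.1627A>G (*5), c.1682G>T, c.1896T>C, c.2194G>A (*6), c.2846A>T	c.1349C>T, c.1682G>T, c.2846A>T
GSTM1	*A	*A, *B, *Ax2 (dup), *0 (del)
GSTP1	*A	*A, *B, *C
GSTT1	*A	*A, *0 (del)
NAT1	*4	*4, *11, *14, *17
NAT2	*4	*4, *5, *6, *7, *12, *13, *14, *24	*24
SLC15A2	*1	*1, *2
SLC22A2	*1	*1, *2, *3, *4, *6, *7, *S1 (del), *S2 (del)
SLCO1B1	*1A	*1A, *1B, *5, *14, *15, *17, *20, *21, *24, *27, *30, *31, *32, *S1, *S2	*20, *32
SLCO2B1	*1	*1, *S1, *S464F
TPMT	*1	*1, *3C, *8, *16
UGT1A1	*1	*1, *6, *28, *36, *80, *80+*28, *80+*37	*80+*27, *80+*37
UGT2B7	*1	*1, *2, *3
UGT2B15	*1	*1, *2, *4, *5, *S1 (del)
UGT2B17	*1	*1, *2 (del)
VKORC1	Reference	Reference, rs9923231
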