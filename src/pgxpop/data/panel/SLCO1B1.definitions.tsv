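#gene=SLCO1B1
#ref=*1
allele	core	12:21329738:A:G:rs2306283	12:21331549:T:C:rs4149056	12:21319842:G:A:rs4149015	12:21331629:G:C:rs59502379
*1		0	0	0	0
*5		0	1	0	0
*15		1	1	0	0
*17		1	1	1	0
*31		1	1	0	1
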