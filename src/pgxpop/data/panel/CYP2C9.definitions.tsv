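#gene=CYP2C9
#ref=*1
allele	core	10:96702047:C:T:rs1799853	10:96741053:A:C:rs1057910	10:96731043:A:G:rs2256871	10:96740981:C:T:rs28371685
*1		0	0	0	0
*2		1	0	0	0
*3		0	1	0	0
*9		0	0	1	0
*11		0	0	0	1
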