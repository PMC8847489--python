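#gene=CYP2D6
#ref=*1
allele	core	22:42523943:G:A:rs16947	22:42524947:C:T:rs3892097	22:42526694:G:A:rs1065852	22:42523805:C:T:rs28371725	22:42526763:C:T:rs28371706
*1		0	0	0	0	0
*2		1	0	0	0	0
*4		0	1	1	0	0
*10		0	0	1	0	0
*17		1	0	0	0	1
*41		1	0	0	1	0
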