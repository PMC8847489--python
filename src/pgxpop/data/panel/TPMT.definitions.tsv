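#gene=TPMT
#ref=*1
allele	core	6:18143955:C:G:rs1800462	6:18139228:C:T:rs1800460	6:18130918:T:C:rs1142345
*1		0	0	0
*2		1	0	0
*3A		0	1	1
*3B		0	1	0
*3C		0	0	1
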