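#gene=CYP2B6
#ref=*1
allele	core	19:41497274:C:T:rs8192709	19:41512841:G:T:rs3745274	19:41515263:A:G:rs2279343	19:41518221:T:C:rs28399499	19:41496461:T:C:rs34223104
*1		0	0	0	0	0
*2		1	0	0	0	0
*4		0	0	1	0	0
*6		0	1	1	0	0
*9		0	1	0	0	0
*18		0	0	0	1	0
*22		0	0	0	0	1
*36		0	1	1	1	0
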