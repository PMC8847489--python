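#gene=DPYD
#ref=*1
allele	core	1:97915614:C:T:rs3918290	1:97981343:A:C:rs55886062
*1		0	0
*2A		1	0
*13		0	1
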