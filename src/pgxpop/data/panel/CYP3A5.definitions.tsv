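#gene=CYP3A5
#ref=*1
allele	core	7:99270539:T:C:rs776746	7:99262835:C:T:rs10264272	7:99250393:A:AT:rs41303343
*1		0	0	0
*3		1	0	0
*6		0	1	0
*7		0	0	1
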