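#gene=NUDT15
#ref=*1
allele	core	13:48611934:C:T:rs116855232	13:48611918:G:GGAGTC:rs554405994
*1		0	0
*2		1	1
*3		1	0
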