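#gene=CYP2C19
#ref=*1
allele	core	10:96541616:G:A:rs4244285	10:96540410:G:A:rs4986893	10:96521657:C:T:rs12248560	10:96535173:A:G:rs12769205
*1		0	0	0	0
*2		1	0	0	.
*3		0	1	0	0
*17		0	0	1	0
*35		0	0	0	1
*2.001	*2				
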