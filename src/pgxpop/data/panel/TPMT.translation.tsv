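allele1	allele2	phenotype	ehr_priority
*1	*1	Normal metabolizer	Normal/Routine/Low Risk
*1	*2	Intermediate metabolizer	Abnormal/Priority/High Risk
*1	*3A	Intermediate metabolizer	Abnormal/Priority/High Risk
*1	*3B	Intermediate metabolizer	Abnormal/Priority/High Risk
*1	*3C	Intermediate metabolizer	Abnormal/Priority/High Risk
*2	*2	Poor metabolizer	Abnormal/Priority/High Risk
*2	*3A	Poor metabolizer	Abnormal/Priority/High Risk
*2	*3B	Poor metabolizer	Abnormal/Priority/High Risk
*2	*3C	Poor metabolizer	Abnormal/Priority/High Risk
*3A	*3A	Poor metabolizer	Abnormal/Priority/High Risk
*3A	*3B	Poor metabolizer	Abnormal/Priority/High Risk
*3A	*3C	Poor metabolizer	Abnormal/Priority/High Risk
*3B	*3B	Poor metabolizer	Abnormal/Priority/High Risk
*3B	*3C	Poor metabolizer	Abnormal/Priority/High Risk
*3C	*3C	Poor metabolizer	Abnormal/Priority/High Risk
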