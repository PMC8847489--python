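allele1	allele2	phenotype	ehr_priority
*1	*1	Normal metabolizer	Normal/Routine/Low Risk
*1	*2	Intermediate metabolizer	Abnormal/Priority/High Risk
*1	*3	Intermediate metabolizer	Abnormal/Priority/High Risk
*2	*2	Poor metabolizer	Abnormal/Priority/High Risk
*2	*3	Poor metabolizer	Abnormal/Priority/High Risk
*3	*3	Poor metabolizer	Abnormal/Priority/High Risk
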