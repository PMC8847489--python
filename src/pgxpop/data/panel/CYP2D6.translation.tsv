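allele1	allele2	phenotype	ehr_priority
*1	*1	Normal metabolizer	Normal/Routine/Low Risk
*1	*2	Normal metabolizer	Normal/Routine/Low Risk
*1	*4	Intermediate metabolizer	Abnormal/Priority/High Risk
*1	*5	Intermediate metabolizer	Abnormal/Priority/High Risk
*1	*10	Normal metabolizer	Normal/Routine/Low Risk
*1	*17	Normal metabolizer	Normal/Routine/Low Risk
*1	*41	Normal metabolizer	Normal/Routine/Low Risk
*1	*1×2	Ultrarapid metabolizer	Abnormal/Priority/High Risk
*1	*2×2	Ultrarapid metabolizer	Abnormal/Priority/High Risk
*1	*36 + *10	Normal metabolizer	Normal/Routine/Low Risk
*1	*68 + *4	Intermediate metabolizer	Abnormal/Priority/High Risk
*2	*2	Normal metabolizer	Normal/Routine/Low Risk
*2	*4	Intermediate metabolizer	Abnormal/Priority/High Risk
*2	*5	Intermediate metabolizer	Abnormal/Priority/High Risk
*2	*10	Normal metabolizer	Normal/Routine/Low Risk
*2	*17	Normal metabolizer	Normal/Routine/Low Risk
*2	*41	Normal metabolizer	Normal/Routine/Low Risk
*2	*1×2	Ultrarapid metabolizer	Abnormal/Priority/High Risk
*2	*2×2	Ultrarapid metabolizer	Abnormal/Priority/High Risk
*2	*36 + *10	Normal metabolizer	Normal/Routine/Low Risk
*2	*68 + *4	Intermediate metabolizer	Abnormal/Priority/High Risk
*4	*4	Poor metabolizer	Abnormal/Priority/High Risk
*4	*5	Poor metabolizer	Abnormal/Priority/High Risk
*4	*10	Intermediate metabolizer	Abnormal/Priority/High Risk
*4	*17	Intermediate metabolizer	Abnormal/Priority/High Risk
*4	*41	Intermediate metabolizer	Abnormal/Priority/High Risk
*4	*1×2	Normal metabolizer	Normal/Routine/Low Risk
*4	*2×2	Normal metabolizer	Normal/Routine/Low Risk
*4	*36 + *10	Intermediate metabolizer	Abnormal/Priority/High Risk
*4	*68 + *4	Poor metabolizer	Abnormal/Priority/High Risk
*5	*5	Poor metabolizer	Abnormal/Priority/High Risk
*5	*10	Intermediate metabolizer	Abnormal/Priority/High Risk
*5	*17	Intermediate metabolizer	Abnormal/Priority/High Risk
*5	*41	Intermediate metabolizer	Abnormal/Priority/High Risk
*5	*1×2	Normal metabolizer	Normal/Routine/Low Risk
*5	*2×2	Normal metabolizer	Normal/Routine/Low Risk
*5	*36 + *10	Intermediate metabolizer	Abnormal/Priority/High Risk
*5	*68 + *4	Poor metabolizer	Abnormal/Priority/High Risk
*10	*10	Intermediate metabolizer	Abnormal/Priority/High Risk
*10	*17	Intermediate metabolizer	Abnormal/Priority/High Risk
*10	*41	Intermediate metabolizer	Abnormal/Priority/High Risk
*10	*1×2	Normal metabolizer	Normal/Routine/Low Risk
*10	*2×2	Normal metabolizer	Normal/Routine/Low Risk
*10	*36 + *10	Intermediate metabolizer	Abnormal/Priority/High Risk
*10	*68 + *4	Intermediate metabolizer	Abnormal/Priority/High Risk
*17	*17	Intermediate metabolizer	Abnormal/Priority/High Risk
*17	*41	Intermediate metabolizer	Abnormal/Priority/High Risk
*17	*1×2	Ultrarapid metabolizer	Abnormal/Priority/High Risk
*17	*2×2	Ultrarapid metabolizer	Abnormal/Priority/High Risk
*17	*36 + *10	Intermediate metabolizer	Abnormal/Priority/High Risk
*17	*68 + *4	Intermediate metabolizer	Abnormal/Priority/High Risk
*41	*41	Intermediate metabolizer	Abnormal/Priority/High Risk
*41	*1×2	Normal metabolizer	Normal/Routine/Low Risk
*41	*2×2	Normal metabolizer	Normal/Routine/Low Risk
*41	*36 + *10	Intermediate metabolizer	Abnormal/Priority/High Risk
*41	*68 + *4	Intermediate metabolizer	Abnormal/Priority/High Risk
*1×2	*1×2	Ultrarapid metabolizer	Abnormal/Priority/High Risk
*1×2	*2×2	Ultrarapid metabolizer	Abnormal/Priority/High Risk
*1×2	*36 + *10	Normal metabolizer	Normal/Routine/Low Risk
*1×2	*68 + *4	Normal metabolizer	Normal/Routine/Low Risk
*2×2	*2×2	Ultrarapid metabolizer	Abnormal/Priority/High Risk
*2×2	*36 + *10	Normal metabolizer	Normal/Routine/Low Risk
*2×2	*68 + *4	Normal metabolizer	Normal/Routine/Low Risk
*36 + *10	*36 + *10	Intermediate metabolizer	Abnormal/Priority/High Risk
*36 + *10	*68 + *4	Intermediate metabolizer	Abnormal/Priority/High Risk
*68 + *4	*68 + *4	Poor metabolizer	Abnormal/Priority/High Risk
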