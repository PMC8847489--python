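allele1	allele2	phenotype	ehr_priority
*1	*1	Normal metabolizer	Normal/Routine/Low Risk
*1	*2	Normal metabolizer	Normal/Routine/Low Risk
*1	*4	Rapid metabolizer	Normal/Routine/Low Risk
*1	*6	Intermediate metabolizer	Abnormal/Priority/High Risk
*1	*9	Intermediate metabolizer	Abnormal/Priority/High Risk
*1	*18	Intermediate metabolizer	Abnormal/Priority/High Risk
*1	*22	Rapid metabolizer	Normal/Routine/Low Risk
*1	*36	Intermediate metabolizer	Abnormal/Priority/High Risk
*2	*2	Normal metabolizer	Normal/Routine/Low Risk
*2	*4	Rapid metabolizer	Normal/Routine/Low Risk
*2	*6	Intermediate metabolizer	Abnormal/Priority/High Risk
*2	*9	Intermediate metabolizer	Abnormal/Priority/High Risk
*2	*18	Intermediate metabolizer	Abnormal/Priority/High Risk
*2	*22	Rapid metabolizer	Normal/Routine/Low Risk
*2	*36	Intermediate metabolizer	Abnormal/Priority/High Risk
*4	*4	Ultrarapid metabolizer	Normal/Routine/Low Risk
*4	*6	Intermediate metabolizer	Abnormal/Priority/High Risk
*4	*9	Intermediate metabolizer	Abnormal/Priority/High Risk
*4	*18	Intermediate metabolizer	Abnormal/Priority/High Risk
*4	*22	Ultrarapid metabolizer	Normal/Routine/Low Risk
*4	*36	Intermediate metabolizer	Abnormal/Priority/High Risk
*6	*6	Poor metabolizer	Abnormal/Priority/High Risk
*6	*9	Poor metabolizer	Abnormal/Priority/High Risk
*6	*18	Poor metabolizer	Abnormal/Priority/High Risk
*6	*22	Intermediate metabolizer	Abnormal/Priority/High Risk
*6	*36	Poor metabolizer	Abnormal/Priority/High Risk
*9	*9	Poor metabolizer	Abnormal/Priority/High Risk
*9	*18	Poor metabolizer	Abnormal/Priority/High Risk
*9	*22	Intermediate metabolizer	Abnormal/Priority/High Risk
*9	*36	Poor metabolizer	Abnormal/Priority/High Risk
*18	*18	Poor metabolizer	Abnormal/Priority/High Risk
*18	*22	Intermediate metabolizer	Abnormal/Priority/High Risk
*18	*36	Poor metabolizer	Abnormal/Priority/High Risk
*22	*22	Ultrarapid metabolizer	Normal/Routine/Low Risk
*22	*36	Intermediate metabolizer	Abnormal/Priority/High Risk
*36	*36	Poor metabolizer	Abnormal/Priority/High Risk
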