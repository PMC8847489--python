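allele1	allele2	phenotype	ehr_priority
*1	*1	Extensive metabolizer (CYP3A5 expressor)	Abnormal/Priority/High Risk
*1	*3	Intermediate metabolizer (CYP3A5 expressor)	Abnormal/Priority/High Risk
*1	*6	Intermediate metabolizer (CYP3A5 expressor)	Abnormal/Priority/High Risk
*1	*7	Intermediate metabolizer (CYP3A5 expressor)	Abnormal/Priority/High Risk
*3	*3	Poor metabolizer (CYP3A5 non-expressor)	Normal/Routine/Low Risk
*3	*6	Poor metabolizer (CYP3A5 non-expressor)	Normal/Routine/Low Risk
*3	*7	Poor metabolizer (CYP3A5 non-expressor)	Normal/Routine/Low Risk
*6	*6	Poor metabolizer (CYP3A5 non-expressor)	Normal/Routine/Low Risk
*6	*7	Poor metabolizer (CYP3A5 non-expressor)	Normal/Routine/Low Risk
*7	*7	Poor metabolizer (CYP3A5 non-expressor)	Normal/Routine/Low Risk
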