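allele1	allele2	phenotype	ehr_priority
*1	*1	Normal function	Normal/Routine/Low Risk
*1	*5	Decreased function (Increased risk of myopathy)	Abnormal/Priority/High Risk
*1	*15	Decreased function (Increased risk of myopathy)	Abnormal/Priority/High Risk
*1	*17	Decreased function (Increased risk of myopathy)	Abnormal/Priority/High Risk
*1	*31	Decreased function (Increased risk of myopathy)	Abnormal/Priority/High Risk
*5	*5	Poor function (High risk of myopathy)	Abnormal/Priority/High Risk
*5	*15	Poor function (High risk of myopathy)	Abnormal/Priority/High Risk
*5	*17	Poor function (High risk of myopathy)	Abnormal/Priority/High Risk
*5	*31	Poor function (High risk of myopathy)	Abnormal/Priority/High Risk
*15	*15	Poor function (High risk of myopathy)	Abnormal/Priority/High Risk
*15	*17	Poor function (High risk of myopathy)	Abnormal/Priority/High Risk
*15	*31	Poor function (High risk of myopathy)	Abnormal/Priority/High Risk
*17	*17	Poor function (High risk of myopathy)	Abnormal/Priority/High Risk
*17	*31	Poor function (High risk of myopathy)	Abnormal/Priority/High Risk
*31	*31	Poor function (High risk of myopathy)	Abnormal/Priority/High Risk
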