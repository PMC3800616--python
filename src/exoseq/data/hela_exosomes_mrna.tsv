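transcript_id	accession	rna_class	count
SUSD2	NM_019601	mRNA	3172.33
BRWD3	NM_153252	mRNA	501.00
SENP6	NM_015571	mRNA	362.67
FAM59B	NM_001191033	mRNA	355.33
TUBBA4	NM_006087	mRNA	338.33
QRFPR	NM_198179	mRNA	313.33
MDK	NM_001012334	mRNA	307.00
MTRNR2L2	NM_001190470	mRNA	302.00
CWC25	NM_017748	mRNA	266.00
DUSP13	NM_001007272	mRNA	232.00
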