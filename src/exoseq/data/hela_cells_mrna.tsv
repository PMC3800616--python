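transcript_id	accession	rna_class	count
MTRNR2L2	NM_001190470	mRNA	4793.67
MTRNR2L8	NM_001190702	mRNA	2646.33
SETD2	NM_014159	mRNA	544.67
CUX1	NM_001202543	mRNA	475.33
TUBA1C	NM_032704	mRNA	475.33
FXR1	NM_004860	mRNA	363.33
SYT6	NM_001253772	mRNA	319.00
FUS	NM_001170634	mRNA	287.33
MDK	NM_001012334	mRNA	238.67
UBE2S	NM_014501	mRNA	230.33
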