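transcript_id	accession	rna_class	count
hsa-mir-21		miRNA	2015.33
hsa-mir-3160-1		miRNA	1007.33
hsa-mir-4739		miRNA	894.33
hsa-mir-31		miRNA	827.33
hsa-mir-23a		miRNA	783.67
hsa-mir-24-2		miRNA	644.00
hsa-mir-1273a		miRNA	521.67
hsa-mir-30a		miRNA	439.33
hsa-mir-451a		miRNA	371.33
hsa-mir-1273g		miRNA	368.00
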