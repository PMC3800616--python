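transcript_id	accession	rna_class	count
hsa-mir-4279		miRNA	731.00
hsa-mir-1234		miRNA	505.00
hsa-mir-451a		miRNA	410.33
hsa-mir-3665		miRNA	330.33
hsa-mir-4449		miRNA	265.67
hsa-mir-3960		miRNA	240.67
hsa-mir-3160-1		miRNA	238.00
hsa-mir-1273a		miRNA	233.67
hsa-mir-1273g		miRNA	195.33
hsa-mir-92b		miRNA	180.00
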