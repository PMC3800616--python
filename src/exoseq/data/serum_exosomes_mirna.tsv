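transcript_id	accession	rna_class	count
hsa-mir-1246		miRNA	2145.0
hsa-mir-451		miRNA	1837.0
hsa-mir-3934		miRNA	1444.5
hsa-mir-1281		miRNA	1068.5
hsa-mir-3180-1		miRNA	871.0
hsa-mir-4257		miRNA	851.5
hsa-mir-181d		miRNA	687.5
hsa-mir-486		miRNA	593.5
hsa-mir-766		miRNA	580.5
hsa-mir-497		miRNA	565.0
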