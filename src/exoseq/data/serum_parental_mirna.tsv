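transcript_id	accession	rna_class	count
hsa-mir-1246		miRNA	5222.5
hsa-mir-451		miRNA	2163.5
hsa-mir-2115		miRNA	77.0
hsa-mir-1281		miRNA	531.0
hsa-mir-486		miRNA	337.5
hsa-mir-16-1		miRNA	326.0
hsa-mir-3180-1		miRNA	116.5
hsa-mir-4257		miRNA	525.0
hsa-mir-124-1		miRNA	136.0
hsa-mir-3167		miRNA	293.5
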