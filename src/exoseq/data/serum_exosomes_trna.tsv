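transcript_id	accession	rna_class	count
chr6.trna4-ArgTCG		tRNA	2071.0
chr6.trna31-SerGCT		tRNA	1867.0
chr15.trna4-ArgTCG		tRNA	1010.0
chr6.trna14-TyrGTA		tRNA	894.5
chr14.trna19-TyrGTA		tRNA	884.5
chr7.trna7-CysGCA		tRNA	681.5
chr1.trna105-GlnCTG		tRNA	591.0
chr6.trna52-ArgTCT		tRNA	581.0
chr6.trna124-ArgTCG		tRNA	565.5
chr16.trna1-ArgCCG		tRNA	544.5
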