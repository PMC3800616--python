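transcript_id	accession	rna_class	count
chr6.trna31-SerGCT		tRNA	801.0
chr12.trna10-AspGTC		tRNA	718.0
chr6.trna4-ArgTCG		tRNA	661.5
chr15.trna4-ArgTCG		tRNA	475.0
chr14.trna19-TyrGTA		tRNA	364.5
chr6.trna124-ArgTCG		tRNA	237.5
chr6.trna14-TyrGTA		tRNA	223.5
chr12.trna12-AspGTC		tRNA	214.0
chr6.trna145-SerAGA		tRNA	211.0
chr6.trna52-ArgTCT		tRNA	200.5
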