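transcript_id	accession	rna_class	count
chr1.trna109-GluCTC		tRNA	175.33
chr16.trna34-GlyCCC		tRNA	147.33
chr16.trna18-GlyGCC		tRNA	121.67
chr6.trna61-MetCAT		tRNA	101.00
chr17.trna28-CysGCA		tRNA	86.33
chr5.trna5-ValAAC		tRNA	52.67
chr5.trna11-LysCTT		tRNA	48.00
chr1.trna33-GlyGCC		tRNA	35.67
chr17.trna10-GlyTCC		tRNA	33.00
chr13.trna3-GluTTC		tRNA	25.33
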