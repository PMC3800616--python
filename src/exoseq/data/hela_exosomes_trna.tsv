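transcript_id	accession	rna_class	count
chr6.trna61-MetCAT		tRNA	34129.67
chr1.trna109-GluCTC		tRNA	15924.33
chr16.trna18-GlyGCC		tRNA	5696.67
chr1.trna33-GlyGCC		tRNA	2354.33
chr16.trna10-LysCTT		tRNA	2119.67
chr5.trna11-LysCTT		tRNA	2107.33
chr13.trna3-GluTTC		tRNA	1987.00
chr16.trna34-GlyCCC		tRNA	1928.33
chr1.trna54-GluCTC		tRNA	1450.33
chr1.trna124-GlyCCC		tRNA	1365.00
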