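transcript_id	accession	rna_class	count
CCDC96	NM_153376	mRNA	606.5
HGSNAT	NM_152419	mRNA	503.0
TBX22	NM_016954	mRNA	465.0
SIRPG	NM_018556	mRNA	350.0
SIRPG.1	NM_080816	mRNA	340.0
NFIX	NM_002501	mRNA	338.5
GPR126	NM_198569	mRNA	288.0
ILDR2	NM_199351	mRNA	273.5
PAPOLB	NM_020144	mRNA	267.5
SIRPG.2	NM_001039508	mRNA	246.5
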