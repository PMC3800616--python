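transcript_id	accession	rna_class	count
CCDC96	NM_153376	mRNA	251.5
SIRPG	NM_080816	mRNA	240.5
TBX22	NM_016954	mRNA	215.0
RNF223	NM_001205252	mRNA	200.5
SIRPG.1	NM_018556	mRNA	198.0
NFIX	NM_002501	mRNA	198.0
RAP2A	NM_021033	mRNA	174.0
SIRPG.2	NM_001039508	mRNA	154.0
HGSNAT	NM_152419	mRNA	143.0
RBFOX1	NM_001142333	mRNA	129.5
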