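transcript_id	accession	rna_class	count
RNY4	NR_004393	ncRNA	704.5
RNY5	NR_001571	ncRNA	262.0
RNY3	NR_004392	ncRNA	174.0
FLJ33534	NR_040080	ncRNA	167.0
LOC100130673	NR_038454	ncRNA	155.0
LOC100507605	NR_038375	ncRNA	153.0
C20orf173	NR_026933	ncRNA	152.0
LOC100507605.1	NR_038374	ncRNA	139.5
LOC644936	NR_004845	ncRNA	136.0
LOC100507605.2	NR_038376	ncRNA	130.5
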