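transcript_id	accession	rna_class	count
RNY4	NR_004393	ncRNA	1043.5
RNY5	NR_001571	ncRNA	477.0
RNY3	NR_004392	ncRNA	360.0
RNY4P8	NR_033356	ncRNA	177.0
RNU2-1	NR_002716	ncRNA	159.5
RNY1	NR_004391	ncRNA	145.5
RNU12	NR_029422	ncRNA	127.5
C1orf213	NR_033690	ncRNA	101.0
RNU5B-1	NR_002757	ncRNA	71.0
C20orf173	NR_026933	ncRNA	70.5
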