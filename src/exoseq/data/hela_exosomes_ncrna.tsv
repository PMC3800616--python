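transcript_id	accession	rna_class	count
RNY5	NR_001571	ncRNA	8482.67
RNY4	NR_004393	ncRNA	6206.33
RN5S3	NR_023365	ncRNA	2343.67
RNY1	NR_004391	ncRNA	2109.67
RNY4P8	NR_033356	ncRNA	2094.33
RNY3	NR_004392	ncRNA	1119.33
RN7SL2	NR_027260	ncRNA	702.33
SNORD31	NR_002560	ncRNA	619.33
RNU1-5	NR_004400	ncRNA	561.67
RN7SL1	NR_002715	ncRNA	457.33
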