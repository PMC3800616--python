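transcript_id	accession	rna_class	count
SNORA72	NR_002581	ncRNA	3865.67
MALAT1	NR_002819	ncRNA	879.67
RNU1-9	NR_004426	ncRNA	798.00
RN5S1	NR_023363	ncRNA	668.67
RNU2-1	NR_002716	ncRNA	629.00
RN7SL1	NR_002715	ncRNA	581.67
SNORD3C	NR_006881	ncRNA	531.00
VDAC1	NR_036624	ncRNA	437.33
RN7SK	NR_001445	ncRNA	435.33
RN7SL2	NR_027260	ncRNA	425.67
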