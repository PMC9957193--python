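line_id	m1	m2	m3	m4	m5
L1	0	2	NA	2	0
L2	2	0	NA	2	1
L3	1	1	0	0	1
L4	1	1	2	0	2
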