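region	kind	n1	n2	n3	n4	n5	mean	ci_low	ci_high
rib	region	0	2	22	97	87	4.3	3.87	4.72
vertebral body and disc space	region	22	39	53	75	19	3.1	2.17	4.12
first costochondral joint	region	0	2	56	98	52	4.0	3.40	4.53
clavicle	region	0	0	23	105	80	4.3	3.77	4.78
scapula	region	0	1	33	84	60	4.3	3.62	4.92
overall appearance	item	0	4	38	116	50	4.0	3.47	4.57
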