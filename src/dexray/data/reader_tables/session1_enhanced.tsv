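region	kind	n1	n2	n3	n4	n5	mean	ci_low	ci_high
unobscured lung	region	0	2	148	28	30	3.5	2.63	4.47
hilum	region	0	2	155	45	6	3.3	2.94	3.58
minor fissure	region	0	0	167	39	2	3.3	3.14	3.40
heart border	region	0	3	124	65	16	3.4	2.91	3.98
retrocardiac lung	region	0	0	87	67	54	3.8	3.26	4.42
subdiaphragmatic lung	region	0	0	111	44	53	3.7	2.96	4.48
azygoesophageal recess	region	0	7	79	73	49	3.8	3.11	4.46
proximal airway	region	0	1	119	82	6	3.4	3.10	3.78
noise reduction (soft-tissue)	item	0	3	86	84	35	3.7	3.08	4.37
rib	region	0	0	44	80	84	4.2	3.55	4.84
vertebral body and disc space	region	0	0	30	95	83	4.3	3.70	4.82
first costochondral joint	region	0	0	106	79	23	3.6	3.07	4.13
clavicle	region	0	0	65	71	72	4.4	4.09	4.67
scapula	region	0	0	59	43	106	4.2	3.41	5.04
noise reduction (bone)	item	0	1	55	123	29	3.9	3.25	4.48
overall appearance	item	0	3	76	83	46	3.8	3.20	4.45
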