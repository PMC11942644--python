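region	kind	n1	n2	n3	n4	n5	mean	ci_low	ci_high
unobscured lung	region	5	33	91	75	4	3.2	2.84	3.56
hilum	region	0	1	65	137	5	3.7	3.50	3.91
minor fissure	region	0	14	181	13	0	3.0	2.86	3.13
heart border	region	0	18	76	99	15	3.5	3.03	4.05
retrocardiac lung	region	7	76	99	26	0	2.7	2.21	3.17
subdiaphragmatic lung	region	9	69	111	19	0	2.7	2.25	3.10
azygoesophageal recess	region	10	78	102	18	0	2.6	2.32	2.93
proximal airway	region	1	33	108	66	0	3.6	3.39	3.88
overall appearance	item	7	51	77	73	0	3.3	3.00	3.58
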