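transcript_id	control	asthma	p_value
Kbtbd12	11.39	0.76	<0.0001
Kbtbd12	14.37	1.08	<0.0001
Hunk	13.10	1.45	0.0008
Slc6a1	24.04	4.20	0.0006
Vsig4	25.70	4.53	<0.0001
Fstl4	57.58	13.73	<0.0001
Col19a1	32.03	8.25	<0.0001
Trim30d	121.32	34.58	<0.0001
Trim30d	94.45	28.47	<0.0001
Agmo	44.13	13.48	<0.0001
Prg2	22.40	296.72	<0.0001
F10	2.23	31.00	<0.0001
Ascl2	2.65	39.68	<0.0001
9830107B12Rik	0.97	14.54	0.0004
9830107B12Rik	0.97	14.86	0.0003
Irg1	5.78	92.58	<0.0001
9830107B12Rik	0.67	12.84	0.0008
Epx	4.59	88.82	<0.0001
Ear6	1.02	26.46	<0.0001
Ear7	0.69	22.45	<0.0001
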