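transcript_id	control	asthma	p_value
fantom3_E230007F07	8.78	0.61	0.0006
fantom3_4933428M03	14.37	1.08	<0.0001
fantom3_B230105C15	10.41	0.99	0.0005
fantom3_E030028L20	12.64	1.76	0.0003
fantom3_A530047B01	21.82	4.05	<0.0001
fantom3_9230106C11	24.67	5.02	0.0002
fantom3_C130024N02	121.92	26.59	<0.0001
fantom3_9230022E05	100.13	22.58	0.0001
fantom3_D130005M09	37.46	9.67	<0.0001
fantom3_6430516O08	25.14	7.87	0.0006
fantom3_F630107E09	3.96	20.46	0.0001
fantom3_9930009M05	3.87	20.74	0.0006
fantom3_9530065C24	4.89	27.20	0.0001
fantom3_D130059M16	3.25	21.04	<0.0001
fantom3_3021401C12	2.21	23.19	<0.0001
fantom3_I830062N05	5.59	62.54	<0.0001
fantom3_F730001C01	4.58	52.60	<0.0001
fantom3_9830118H07	4.92	58.38	<0.0001
fantom3_E130019F23	1.31	16.65	<0.0001
fantom3_4930418C01	0.33	9.44	<0.0001
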