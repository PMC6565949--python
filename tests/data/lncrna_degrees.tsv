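id	direction	degree
fantom3_3021401C12	up	126
fantom3_4930418C01	up	43
fantom3_9230022E05	down	102
fantom3_9230106C11	down	86
fantom3_9530065C24	up	30
fantom3_9530072G02	up	39
fantom3_9830118H07	up	99
fantom3_A330048C04	down	160
fantom3_C130024N02	down	39
fantom3_D130059M16	up	33
fantom3_E130019F23	up	158
fantom3_F630107E09	up	108
fantom3_F630119J15	up	52
fantom3_F730001C01	up	78
fantom3_A530047B01	down	120
fantom3_I830062N05	up	94
fantom3_4933428M03	down	185
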