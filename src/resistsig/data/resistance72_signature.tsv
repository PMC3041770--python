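probeset	gene	t_value
202840_at	TAF15	5.2
210350_x_at	ING1	4.2
201247_at	SREBF2	3.9
203391_at	FKBP2	3.9
218481_at	EXOSC5	3.8
210014_x_at	IDH3B	3.7
208714_at	NDUFV1	3.7
204133_at	RRP9	3.6
203103_s_at	PRPF19	3.6
212563_at	BOP1	3.6
217874_at	SUCLG1	3.5
208676_s_at	PA2G4	3.5
202339_at	SYMPK	3.4
221809_at	RANBP10	3.4
201487_at	CTSC	3.4
211975_at	ZNF289	3.4
202072_at	HNRNPL	3.3
202649_x_at	RPS19	3.3
209509_s_at	DPAGT1	3.3
208907_s_at	MRPS18B	3.3
221669_s_at	ACAD8	3.3
217940_s_at	FLJ10769	3.3
200980_s_at	PDHA1	3.3
209196_at	WDR46	3.3
210859_x_at	CLN3	3.2
202926_at	NAG	3.2
200824_at	GSTP1	3.2
219979_s_at	C11orf73	3.2
208101_s_at	URM1	3.1
208950_s_at	ALDH7A1	3.1
200874_s_at	NOL5A	3.1
203039_s_at	NDUFS1	3.1
201732_s_at	CLCN3	3.1
202699_s_at	TMEM63A	3.1
200834_s_at	RPS21	3.1
201871_s_at	LOC51035	3.0
200901_s_at	M6PR	3.0
210416_s_at	CHEK2	3.0
37950_at	PREP	3.0
209134_s_at	RPS6	3.0
208619_at	DDB1	3.0
33132_at	CPSF1	3.0
217792_at	SNX5	3.0
202857_at	TMEM4	3.0
211595_s_at	MRPS11	3.0
209147_s_at	PPAP2A	2.9
200812_at	CCT7	2.9
201039_s_at	RAD23A	2.9
209029_at	COPS7A	2.9
201391_at	TRAP1	2.9
200658_s_at	PHB	2.9
212357_at	KIAA0280	2.9
218405_at	ABT1	2.9
200637_s_at	PTPRF	2.9
218049_s_at	MRPL13	2.9
212191_x_at	RPL13	2.9
200695_at	PPP2R1A	2.8
201834_at	PRKAB1	2.8
218866_s_at	POLR3K	2.8
213175_s_at	SNRPB	2.8
210027_s_at	APEX1	2.8
218670_at	PUS1	2.8
209669_s_at	SERBP1	2.8
212032_s_at	PTOV1	2.8
200022_at	RPL18	2.8
200819_s_at	RPS15	2.8
204175_at	ZNF593	2.8
209224_s_at	NDUFA2	2.8
209148_at	RXRB	2.8
216105_x_at	PPP2R4	2.8
217753_s_at	RPS26	2.8
221475_s_at	RPL15	2.8
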