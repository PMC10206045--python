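name	gene_id	group	orf_aa	heptapeptides	zf_type	domain_number	gene_type	at_ortholog
RsWRKY1	Rhsim01G0033600	I	397	WRKYGQK;WRKYGQK	C2H2	2	Dispersed	AT4G30935
RsWRKY2	Rhsim01G0241100	I	548	WRKYGEK;WRKYGQK	C2H2	2	WGD	AT2G38470
RsWRKY3	Rhsim01G0268400	III	346	WRKYGQK	Lost	1	Transposed	AT5G28650
RsWRKY4	Rhsim02G0002700	IIc	213	WRKYGQK	C2H2	1	WGD	At1G64000
RsWRKY5	Rhsim02G0146200	IIe	293	WRKYGQK	C2H2	1	Transposed	At2G34830
RsWRKY6	Rhsim02G0213700	IIa	316	WRKYGQK	C2H2	1	Tandem	At4G31800
RsWRKY7	Rhsim02G0213800	IIa	291	WRKYGQK	C2H2	1	Tandem	At2G25000
RsWRKY8	Rhsim03G0153300	III	315	WRKYGQK	C2HC	1	WGD	At1G80590
RsWRKY9	Rhsim03G0192300	IIe	365	WRKYGQK	C2H2	1	WGD	At5G52830
RsWRKY10	Rhsim03G0198800	III	382	WRKYGQK	C2HC	1	WGD	AT4G23810
RsWRKY11	Rhsim04G0007000	I	669	WRKYGQK;WRKYGQK	C2H2	2	WGD	AT5G56270
RsWRKY12	Rhsim04G0015000	I	595	WRKYGQK	C2H2	2	WGD	AT4G26640
RsWRKY13	Rhsim04G0052400	IIb	578	WRKYGQK	C2H2	1	WGD	At1G68150
RsWRKY14	Rhsim04G0158500	IIc	292	WRKYGQK	C2H2	1	Dispersed	AT5G64810
RsWRKY15	Rhsim04G0240600	IIc	328	WRKYGQK	C2H2	1	WGD	AT5G13080
RsWRKY16	Rhsim05G0168200	I	545	WRKYGQK;WRK--------	C2H2	2	Transposed	AT2G38470
RsWRKY17	Rhsim05G0226500	I	351	WRKYGQK	C2H2	2	WGD	AT2G38470
RsWRKY18	Rhsim05G0231400	III	330	WRKYGQK	C2HC	1	WGD	At1G66560
RsWRKY19	Rhsim05G0231500	III	410	WRKYGQK	C2HC	1	Tandem	AT5G22570
RsWRKY20	Rhsim06G0054700	IId	331	WRKYGQK	C2H2	1	WGD	At4G24240
RsWRKY21	Rhsim06G0156700	IIe	429	WRKYGRK	C2H2	1	Transposed	AT5G45270
RsWRKY22	Rhsim06G0164400	IIb	540	WRKYGQK	C2H2	1	WGD	At1G18860
RsWRKY23	Rhsim06G0174100	I	476	WRKYGQK;WRKYGQK	C2H2	2	Dispersed	AT4G26640
RsWRKY24	Rhsim06G0220000	IIb	478	WRKYGQK	C2H2	1	WGD	At1G69810
RsWRKY25	Rhsim06G0226600	I	681	WRKYGQK;WRKYGQK	C2H2	2	WGD	AT4G26640
RsWRKY26	Rhsim06G0235700	I	716	WRKYGQK;WRKYGQK	C2H2	2	WGD	AT5G56270
RsWRKY27	Rhsim07G0005900	III	327	WRKYGQK	C2HC	1	WGD	AT4G11070
RsWRKY28	Rhsim07G0009800	IIc	223	WRKYGQK	C2H2	1	WGD	AT3G01970
RsWRKY29	Rhsim07G0010600	IIe	325	WRKYGQK	C2H2	1	WGD	At1G30650
RsWRKY30	Rhsim07G0037500	IIc	125	WRKYGQK	C2H2	1	Transposed	At5G46350
RsWRKY31	Rhsim07G0083100	III	351	WRKYGQK	C2HC	1	WGD	At2G46400
RsWRKY32	Rhsim07G0087300	III	129	WRKYGQK	Lost	1	WGD	At4G18170
RsWRKY33	Rhsim07G0225700	IId	343	WRKYGQK	C2H2	1	WGD	At2G23320
RsWRKY34	Rhsim08G0072700	I	557	WRKYGQK;WRKYGQK	C2H2	2	Dispersed	AT1G13960
RsWRKY35	Rhsim08G0098300	IId	368	WRKYGQK	C2H2	1	WGD	At2G30590
RsWRKY36	Rhsim08G0158800	IIb	559	WRKYGQK	C2H2	1	Dispersed	At4G22070
RsWRKY37	Rhsim08G0205900	IIa	330	WRKYGQK	C2H2	1	WGD	At1G80840
RsWRKY38	Rhsim10G0005100	IIc	176	WRKYGQK	C2H2	1	Dispersed	At4G39410
RsWRKY39	Rhsim10G0147700	IIc	264	WRKYGQK	C2H2	1	Proximal	At2G47260
RsWRKY40	Rhsim11G0062500	III	227	WRKYGQK	C2HC	1	Tandem	AT5G01900
RsWRKY41	Rhsim11G0064200	III	214	WRQCRRK	C2HC	1	Transposed	At1G66550
RsWRKY42	Rhsim11G0120500	III	1671	WRKYGQK	Lost	1	Tandem	At5G24110
RsWRKY43	Rhsim12G0007700	IIc	325	WRKYGQK	C2H2	1	Transposed	At2G46130
RsWRKY44	Rhsim12G0077700	I	535	WRKYGQK;WRKYGQK	C2H2	2	Dispersed	AT1G13960
RsWRKY45	Rhsim12G0094500	IIc	184	WRKYGQK	C2H2	1	Dispersed	At2G44745
RsWRKY46	Rhsim12G0134800	IIc	471	WRKYGQK	C2H2	1	Dispersed	At5G41570
RsWRKY47	Rhsim12G0187400	IIa	331	WRKYGQK	C2H2	1	WGD	At5G15130
RsWRKY48	Rhsim13G0003300	IIc	333	WRKYGQK	C2H2	1	Dispersed	AT5G49520
RsWRKY49	Rhsim13G0061600	IId	353	WRKYGQK	C2H2	1	Transposed	AT3G04670
RsWRKY50	Rhsim13G0063200	I	562	WRKYGQK;WRKYGQK	C2H2	2	WGD	AT2G38470
RsWRKY51	Rhsim13G0125600	IIe	484	WRKYGQK	C2H2	1	Transposed	AT5G45050
RsWRKY52	Rhsim13G0151900	IIb	583	WRKYGQK	C2H2	1	WGD	At1G62300
RsWRKY53	Rhsim13G0187900	IIe	271	WRKYGQK	C2H2	1	Transposed	AT4G23550
RsWRKY54	RhsimUnG0056300	IIb	541	WRKYGQK	C2H2	1	Transposed	AT4G01720
RsWRKY55	RhsimUnG0080500	III	547	WRKYGQK	Lost	1	Dispersed	AT3G56400
RsWRKY56	RhsimUnG0083000	III	268	WRKYGQK	C2HC	1	Dispersed	At2G40740
RsWRKY57	RhsimUnG0199600	IIb	566	WRKYGQK	C2H2	1	Transposed	At4G04450
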