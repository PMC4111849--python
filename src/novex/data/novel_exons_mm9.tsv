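id	gene	position	length	strand	protein	prediction
hNE-1	Cluh	chr11:74467029-74467303	275	+	Q5SW19	38 AA shorter
hNE-2	Mylk4	chr13:32820204-32820624	421	-	Q5SUV5	
hNE-3	Clasp1	chr1:120451862-120451963	102	+		
hNE-4	Schip1	chr3:68388089-68388346	258	+	Q3TI53	27 AA different
hNE-5	Mylk4	chr13:32868030-32868501	472	+	Q5SUV5	85 AA different
hNE-6	Mylk4	chr13:32818712-32819001	290	+	Q5SUV5	
hNE-7	Clasp1	chr1:120378050-120378669	620	+		
hNE-8	Trdn	chr10:33086092-33087214	1123	+		Same as 51 kDa skeletal Trdn
hNE-9	Sorbs1	chr19:40452144-40452869	726	-	Q62417	241 AA longer
hNE-10	Csde1	chr3:102840498-102840644	147	+	Q91W50	46 AA longer
hNE-11	Larp5	chr13:9127241-9130370	3130	+	Q80UQ3	105 AA longer
hNE-12	Nedd5l	chr18:65243095-65244448	1354	+		
hNE-13	Nexn	chr3:151927873-151928180	308	-	Q7TPW1	
tNE-1	Lrrc8b	chr5:105881814-105883128	1315	+	Q5DU41	Different 5'UTR
tNE-2	Eya4	chr10:22905057-22905389	333	-	Q9Z191	Different 5'UTR
tNE-3	Skp2	chr15:9082539-9082780	242	-	Q9Z0Z3	Different 5'UTR
tNE-4	Fam71d	chr12:79824797-79824939	143	+	D3YV92	26 shorter AA, different C term
tNE-5	Fam71d	chr12:79796826-79797030	205	+	D3YV92	Different 5'UTR
tNE-6	Rfx1	chr8:86608465-86608794	330	+		
tNE-7	Fam71d	chr12:79823117-79823280	164	+	D3YV92	
tNE-8	Pfkm	chr15:97925522-97925641	120	+	Q1LZL7	70 AA longer
tNE-9	Scamp2	chr9:57426081-57426209	129	+	Q9ERN0	44 AA longer
tNE-10	Pkm2	chr9:59510847-59510963	117	+	P52480	Different 5'UTR
tNE-11	Vapa	chr17:65936384-65936506	123	-	Q9WV55	41 AA longer
tNE-12	Eya4	chr10:22903219-22903421	203	-	Q9Z191	Different 5'UTR
tNE-13	Efr3a	chr15:65696232-65696453	222	+	Q8BG67	131 AA shorter (C-term)
tNE-14	1700001C02Rik	chr5:30779031-30779154	124	+	Q9DAS2	N-term 15 AA
tNE-15	Mtmr6	chr14:60909543-60909656	114	+	Q8VE11	38 AA longer
tNE-16	Mbtd1	chr11:93800835-93801026	192	+		
tNE-17	Ms4a5	chr19:11352451-11352587	137	-	Q810P8	C-term 97 AA shorter
tNE-18	Zfp385a	chr15:103151501-103151619	119	-	Q8VD12	N-term 50 AA shorter
tNE-19	1700025F22Rik	chr19:11233536-11233685	150	-	Q6P8I0	56 AA longer
tNE-20	Higd1a	chr9:121765839-121765990	152	-	Q9JLR9	Different 5'UTR
tNE-21	Pkm2	chr9:59506806-59506960	155	+	P52480	Different 5'UTR
tNE-22	Dnahc2	chr11:69331069-69331230	162	-	Q9P225	54 AA longer
tNE-23	1700006A11Rik	chr3:124105142-124105398	257	-	B9EHI3	71 AA longer (C-term)
tNE-24	Zfand6	chr7:91790796-91790947	152	-	Q9DCH6	Different 5'UTR
tNE-25	Pcbp2	chr15:102303428-102303532	105	+	Q61990	Different 5'UTR
tNE-26	Eya4	chr10:22902544-22902630	87	-	Q9Z191	31 AA shorter
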