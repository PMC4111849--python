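id	position	n_exons	tissue	p_value_min	p_value_max	protein	non_mouse_gene	est
tNT-1	chr1:99242925-99375659+	13	Testis	2.82E-10	2.38E-06	XP_001475034.3	Slc06d1	
tNT-2	chr1:163105753-163167403+	18	Testis	2.17E-07	0.000138	XP_344166.4	Slc9c2	
tNT-3	chr1:121786157-121796422-	5	Testis	0.000605	0.0083	NP_001102853		
tNT-4	chr10:86118523-86133752+	9	Testis	6.79E-07	6.28E-05	XP_487135.3		
tNT-5	chr10:85157135-85173678-	10	Testis	4.18E-05	0.002125	XP_896558.3		
tNT-6	chr10:85989049-86004244-	9	Testis	2.73E-07	9.99E-06	XP_896769.1		
tNT-7	chr10:111578812-111597369-	6	Testis	1.13E-06	0.000297	XP_001480681.1		
tNT-8	chr13:56527964-56535585+	5	Testis	1.49E-08	1.44E-05	XP_001475551	RGD1562024	O
tNT-9	chr13:97569388-97679749+	17	Testis	3.30E-08	2.86E-06	XP_005065555	Ankrd31	O
tNT-10	chr15:25984096-25992242-	5	Testis	0.000857	0.014133			O
tNT-11	chr15:76363652-76365439-	5	Testis	1.13E-08	5.45E-05	XP_988010.2	Tmem249	O
tNT-12	chr18:13666918-13682257+	5	Testis	0.000183	0.005416	YP_480919		
tNT-13	chr18:32317886-32322406-	5	Testis	4.44E-07	0.000236	WP_005016571		O
tNT-14	chr18:32617748-32622397-	8	Testis	0.000202	0.014407	ELW62217		O
tNT-15	chr19:40823242-40903550+	22	Testis	4.82E-08	0.001078	XP_004749675		O
tNT-16	chr2:170290671-170296220-	5	Testis	4.46E-08	0.000182	XP_004246409		O
tNT-17	chr2:173112853-173116672-	5	Testis	1.93E-06	0.00039	YP_003981506		O
tNT-18	chr3:31543868-31589424-	14	Testis	1.07E-07	6.66E-05	NP_001028651.1		
tNT-19	chr5:28278582-28303869+	6	Testis	6.41E-11	1.92E-06	XP_003085546		
tNT-20	chr5:129869449-129872910+	5	Testis	9.84E-09	2.13E-05	YP_001641156		O
tNT-21	chr5:117435484-117468048-	5	Testis	0.000816	0.017383	XP_001524870.1		O
tNT-22	chr6:16406558-16419928-	6	Testis	7.12E-05	0.00307			O
tNT-23	chr6:44030493-44033356-	5	Testis	0.001282	0.018015			O
tNT-24	chr7:120126477-120132935+	5	Testis	0.004419	0.041732	EGV91268		O
tNT-25	chr7:127696533-127711472+	5	Testis	7.17E-05	0.002835	EDL17209.1		O
tNT-26	chr7:36029889-36060558-	10	Testis	1.14E-08	4.01E-06	XP_001480194	WDR88	
tNT-27	chr8:74348600-74377254-	11	Testis	9.06E-06	0.001105	EDL28738		O
tNT-28	chrX:98891146-98901100+	5	Testis	0.00037	0.034496	XP_005095122		
tNT-29	chrX:43597928-43606686-	5	Testis	1.97E-10	1.94E-06			
tNT-30	chr12:44067864-44135252-	5	Testis	0.002254	0.017821	EDL38698.1		
tNT-31	chr17:14128560-14192168-	6	Testis	6.01E-11	4.13E-06	EDL20486.1		
tNT-32	chr17:21191727-21199635-	6	Testis	7.30E-11	3.14E-06	EDL20488.1		O
lNT-1	chr10:111026064-111048582+	5	Liver	1.19E-05	0.021035	EDL21734.1		O
lNT-2	chr12:73709901-73729881-	6	Liver	4.69E-06	0.009759	XP_003512062.1	Dhrc7	O
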