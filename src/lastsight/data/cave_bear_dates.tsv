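site	country	specimen	lab_code	c14_age	c14_err	cal_mean	cal_sd	cal_median	cal_lo95	cal_hi95	haplotype	conservative_excluded	source
Stajnia Cave	Poland	3rd phalanx	Poz-61719	20930	140	25251	205	25267	25648	24807	U. ingressus	true	Baca et al. 2016
Grotta Sopra Fontana Marella	Italy		UZ-2512/ETH-5I98	21810	200	26082	202	26058	26516	25712		true	Perego et al. 2001
Stajnia Cave	Poland	3rd phalanx	GdA-3894	21900	90	26114	113	26101	26360	25905	U. ingressus	true	Baca et al. 2016
Vindija Cave	Croatia		Beta-171313	22020	100	26235	137	26221	26516	25985	U. ingressus	true	Hofreiter et al. 2004
Szeleta Cave	Hungary	Bone	ISGS-A-0131	22107	130	26331	175	26317	26681	26006		true	Adams 2002
Grotta Sopra Fontana Marella	Italy		UZ-2513/ETH-5199	22310	200	26600	273	26585	27122	26102		true	Perego et al. 2001
Chiostraccio Cave	Italy	Long bone	Beta-285012	22670	130	26990	197	27010	27340	26595		false	Martini et al. 2014
Rebolal Cave	Spain	Adult jaw	Ua-24939	22915	445	27128	429	27161	27886	26202		true	Grandal-d'Anglade et al. 2006
Vindija Cave	Croatia		Beta-156100	23780	120	27851	120	27841	28103	27624	U. ingressus	true	Hofreiter et al. 2002
Rochedane	France	3rd metatarsal	GrA-52632	23900	110	27948	134	27934	28231	27701	U. spelaeus	false	Bocherens et al. 2014
Chiostraccio Cave	Italy	Phalanx	Beta-340969	23930	100	27969	132	27956	28245	27725		false	Martini et al. 2014
Cova Eiros	Spain	Humerus	Ua-4298	24090	440	28237	405	28205	29070	27475		false	Grandal-d'Anglade & Vidal Romani 1997
Bame aux Pirotas	Switzerland	Metapodial frag.	ETH-16879	24170	230	28223	237	28216	28679	27783		false	Morel & Schifferdecker 1997
Barenloch	Austria	Radius	Ua-24796	24175	365	28271	343	28249	28956	27634		false	Bochud et al. 2007
Komarowa Cave	Poland	Skull	Poz-339	24550	220	28582	248	28587	29075	28050		false	Wojtal et al. 2015
Deszczowa Cave	Poland	Mandible frag.	Poz-28284	24580	200	28615	227	28619	29069	28129	U. ingressus	false	Wojtal et al. 2015
Izabela Textorisova Cave	Slovakia	Metacarpal IV	VERA-5679	24640	170	28680	193	28680	29076	28280		false	Sabol et al. 2014
Istallos-ko Cave	Hungary	Caudal vertebra	OxA-16640	24950	140	28997	183	28983	29379	28660		false	Davies & Hedges 2008
Gamssulzenhohle	Austria		VRI-1159	25090	640	29310	699	29266	30696	28002		false	Fiebig & Pacher 2004
Istallos-ko Cave	Hungary	Metacarpal	OxA-16639	25500	210	29659	314	29633	30305	29060		false	Davies & Hedges 2008
Sirgenstein Cave	Germany	m1	OxA-12013	25560	130	29707	224	29681	30199	29310	U. ingressus	false	Hofreiter et al. 2007
Cova Eiros	Spain	Rib	Ua-38460	25592	602	29781	625	29784	30959	28622		false	Perez-Rama et al. 2011
Gamssulzenhohle	Austria		Hv 16893	25965	780	30093	765	30101	31480	28537		false	Withalm 2004
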