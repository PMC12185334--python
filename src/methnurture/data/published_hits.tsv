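probe_id	chromosome	position	predictor_role	trait	gene	n_cis_mqtl	n_gws_snps
cg00974944	3	61649924	maternal	schizophrenia	PTPRG
cg02039858	14	65828769	maternal	schizophrenia
cg03174043	2	20548412	maternal	schizophrenia		185
cg03526788	8	130899478	maternal	schizophrenia	FAM49B
cg04822154	8	124692680	maternal	schizophrenia
cg07980854	20	57586338	maternal	schizophrenia		634
cg09163778	6	31125417	maternal	schizophrenia	TCF19;CCHCR1
cg10365572	5	141245930	maternal	schizophrenia	PCDH1
cg12098069	13	42537172	maternal	schizophrenia	VWA8-AS1
cg12501870	8	81803721	maternal	schizophrenia		182
cg12759387	1	27849177	maternal	schizophrenia		177
cg21028402	6	113932902	maternal	schizophrenia		297
cg22280238	17	79251323	maternal	schizophrenia	SLC38A10
cg26017484	1	3322309	maternal	schizophrenia	PRDM16
cg27277458	10	63597194	maternal	schizophrenia
cg02838980	16	10402487	paternal	schizophrenia
cg01229327	19	54311998	offspring	schizophrenia	NLRP12
cg02530860	8	144371537	offspring	schizophrenia		646
cg03161422	4	175256045	offspring	schizophrenia
cg03836484	10	25349182	offspring	schizophrenia	ENKUR
cg09950681	11	393392	offspring	schizophrenia	PKP3
cg09967523	18	18943072	offspring	schizophrenia	GREB1L
cg12381295	20	3880297	offspring	schizophrenia	PANK2
cg12614148	1	118325026	offspring	schizophrenia		98
cg12823387	1	214614656	offspring	schizophrenia	PTPN14
cg15518113	1	167400121	offspring	schizophrenia	CD247	105
cg15571646	2	238767351	offspring	schizophrenia	RAMP1
cg16739178	16	85470674	offspring	schizophrenia		50
cg17727125	8	38441156	offspring	schizophrenia
cg20516845	21	43823604	offspring	schizophrenia	UBASH3A	140
cg20742175	20	57267357	offspring	schizophrenia	NPEPL1;STX16-NPEPL1
cg20807751	9	84025287	offspring	schizophrenia
cg22889887	11	113433931	offspring	schizophrenia		6
cg23464619	13	95513506	offspring	schizophrenia		50
cg24812103	8	101735630	offspring	schizophrenia	PABPC1	244
cg25607267	12	122362708	offspring	schizophrenia	WDR66
cg27475979	16	89471039	offspring	schizophrenia	ANKRD11
cg14576502	8	102962279	paternal	educational_attainment	NCALD
cg15336177	1	99369228	paternal	educational_attainment	LPPR5
cg04975399	1	67822225	offspring	educational_attainment	IL12RB2
cg05083647	1	204897364	offspring	educational_attainment	NFASC
cg06629713	2	60580559	offspring	educational_attainment		43
cg06565683	20	46817989	maternal	bmi
cg21894669	2	165379442	maternal	height	GRB14
cg22338356	8	48739161	maternal	height	PRKDC
cg01633359	5	33439359	paternal	height		164	56
cg03338154	6	41121714	paternal	height	TREML1
cg12738049	15	76509692	paternal	height	ETFA
cg23975250	22	44757380	paternal	height
cg02319662	4	108127694	offspring	height
cg03480605	7	151038446	offspring	height	NUB1	216	17
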