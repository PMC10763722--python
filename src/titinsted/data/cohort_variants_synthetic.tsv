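sample_id	gene	protein_position	consequence	pathogenicity
DCM001	TTN	17250	p.Arg17250Ter	pathogenic
DCM002	TTN	18940	p.Gln18940Ter	likely_pathogenic
DCM003	TTN	16200	p.Trp16200Ter	pathogenic
DCM003	RAF1	257	p.Ser257Leu	pathogenic
DCM004	TTN	20315	p.Ser20315ValfsTer12	pathogenic
DCM005	TTN	21402	p.Arg21402Ter	novel_truncating
DCM006	TTN	22518	p.Gly22518AlafsTer5	pathogenic
DCM007	TTN	23677	p.Glu23677Ter	likely_pathogenic
DCM007	TRPM4	101	p.Glu101Ter	likely_pathogenic
DCM008	TTN	24820	p.Lys24820AsnfsTer31	novel_truncating
DCM009	TTN	25974	p.Arg25974Ter	pathogenic
DCM010	TTN	27103	p.Leu27103PhefsTer8	pathogenic
DCM011	TTN	28255	p.Arg28255Ter	likely_pathogenic
DCM012	TTN	29390	p.Tyr29390Ter	pathogenic
DCM013	TTN	30528	p.Asp30528GlyfsTer22	novel_truncating
DCM014	TTN	31655	p.Arg31655Ter	pathogenic
DCM015	TTN	32710	p.Ser32710LeufsTer4	likely_pathogenic
DCM016	TTN	33210	p.Gln33210Ter	pathogenic
DCM017	TTN	33770	p.Val33770GlyfsTer17	pathogenic
DCM018	TTN	19950	p.Ile19950MetfsTer9	likely_pathogenic
DCM019	TTN	35700	p.Arg35700Ter	pathogenic
DCM020	LMNA	190	p.Arg190Trp	pathogenic
DCM020	DSP	1040	p.Arg1040Ter	pathogenic
DCM021	LMNA	453	p.Arg453Trp	pathogenic
DCM022	LMNA	535	p.Arg535Cys	likely_pathogenic
DCM023	LMNA	60	p.Glu60GlyfsTer12	pathogenic
DCM024	DSP	2120	p.Gln2120Ter	pathogenic
DCM024	BAG3	470	p.Pro470Ser	likely_pathogenic
DCM025	DSP	330	p.Ser330PhefsTer20	pathogenic
DCM026	DSP	1490	p.Arg1490Lys	likely_pathogenic
DCM027	BAG3	209	p.Pro209Leu	pathogenic
DCM028	FKTN	310	p.Arg310Ter	likely_pathogenic
DCM029	LAMA2	2450	p.Cys2450Ter	pathogenic
DCM030	MYBPC3	502	p.Trp502Ter	pathogenic
DCM031	MYH6	1120	p.Arg1120Gln	likely_pathogenic
DCM032	MYH7	723	p.Arg723Gly	pathogenic
DCM033	PLN	9	p.Arg9Cys	pathogenic
DCM034	RBM20	634	p.Arg634Gln	pathogenic
DCM035	TNNI3	145	p.Arg145Trp	likely_pathogenic
DCM036	KCNQ1	341	p.Arg341Trp	likely_pathogenic
DCM037	KCNH2	534	p.Arg534Cys	pathogenic
DCM038	SCN5A	1623	p.Arg1623Ter	pathogenic
DCM039	RYR2	2386	p.Gly2386Ser	likely_pathogenic
DCM040	PKP2	672	p.Arg672GlyfsTer9	pathogenic
DCM041	FBN1	1027	p.Cys1027Tyr	likely_pathogenic
DCM042	LDLR	350	p.Glu350Lys	pathogenic
DCM043	KCNQ1	190	p.Val190MetfsTer4	likely_pathogenic
DCM044	MYLK2	324	p.Arg324Ter	likely_pathogenic
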