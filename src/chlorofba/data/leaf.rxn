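# leaf_reduced: 121 metabolites, 108 reactions
# id	equation	lb ub	subsystem	gpr
Photon_tx	x_Photon -> chl_Photon	0 10000	light	
chl_LightNonCyclic	8 chl_Photon + 2 chl_NADP + 2 chl_ADP + 2 chl_Pi -> 2 chl_NADPH + 2 chl_ATP + chl_O2	0 10000	light	
chl_LightCyclic	2 chl_Photon + chl_ADP + chl_Pi -> chl_ATP + chl_H2O	0 10000	light	
chl_RuBisCO_carb	chl_RuBP + chl_CO2 + chl_H2O -> 2 chl_PGA	0 1000	calvin	OsRBCS AND OsRBCL
chl_RuBisCO_oxy	chl_RuBP + chl_O2 -> chl_PGA + chl_PGlyc	0 1000	calvin	OsRBCS AND OsRBCL
chl_PGK	chl_PGA + chl_ATP -> chl_BPG + chl_ADP	0 1000	calvin	
chl_GAPDH	chl_BPG + chl_NADPH -> chl_GAP + chl_NADP + chl_Pi	0 1000	calvin	
chl_TPI	chl_GAP <> chl_DHAP	-1000 1000	calvin	
chl_FBA	chl_GAP + chl_DHAP -> chl_FBP	0 1000	calvin	
chl_FBPase	chl_FBP + chl_H2O -> chl_F6P + chl_Pi	0 1000	calvin	
chl_TK1	chl_F6P + chl_GAP -> chl_X5P + chl_E4P	0 1000	calvin	
chl_SBA	chl_E4P + chl_DHAP -> chl_SBP	0 1000	calvin	
chl_SBPase	chl_SBP + chl_H2O -> chl_S7P + chl_Pi	0 1000	calvin	
chl_TK2	chl_S7P + chl_GAP -> chl_X5P + chl_R5P	0 1000	calvin	
chl_RPE	chl_X5P <> chl_Ru5P	-1000 1000	calvin	
chl_RPI	chl_R5P <> chl_Ru5P	-1000 1000	calvin	
chl_PRK	chl_Ru5P + chl_ATP -> chl_RuBP + chl_ADP	0 1000	calvin	
chl_PGM_ENO	chl_PGA <> chl_PEP + chl_H2O	-1000 1000	glycolysis	
chl_PK	chl_PEP + chl_ADP -> chl_Pyr + chl_ATP	0 1000	glycolysis	
chl_PEPC	chl_PEP + chl_CO2 + chl_H2O -> chl_OAA + chl_Pi	0 1000	anaplerosis	
chl_MDH	chl_OAA + chl_NADPH -> chl_Mal + chl_NADP	0 1000	anaplerosis	
chl_PPase	chl_PPi + chl_H2O -> 2 chl_Pi	0 1000	housekeeping	
chl_GluALA	chl_Glu + chl_ATP + chl_NADPH -> chl_ALA + chl_ADP + chl_Pi + chl_NADP	0 1000	tetrapyrrole	OsHEMA AND OsGSA
chl_ALAD	2 chl_ALA -> chl_PBG + 2 chl_H2O	0 1000	tetrapyrrole	OsALAD
chl_HMBS	4 chl_PBG + chl_H2O -> chl_HMB + 4 chl_NH3	0 1000	tetrapyrrole	OsPBGD
chl_UROS	chl_HMB -> chl_UroIII + chl_H2O	0 1000	tetrapyrrole	
chl_UROD	chl_UroIII -> chl_CoproIII + 4 chl_CO2	0 1000	tetrapyrrole	
chl_CPO	chl_CoproIII + chl_O2 -> chl_ProtogenIX + 2 chl_CO2 + 2 chl_H2O	0 1000	tetrapyrrole	OsCPO
chl_PPO	chl_ProtogenIX + 1.5 chl_O2 -> chl_ProtoIX + 3 chl_H2O	0 1000	tetrapyrrole	OsPPO
chl_MgCh	chl_ProtoIX + chl_ATP + chl_H2O -> chl_MgPP + chl_ADP + chl_Pi	0 1000	tetrapyrrole	OsCHLH AND OsCHLI AND OsCHLD
chl_CHLM	chl_MgPP + chl_SAM -> chl_MgPPME + chl_AdoHcy	0 1000	tetrapyrrole	OsCHLM
chl_CYC	chl_MgPPME + chl_O2 + chl_NADPH -> chl_DVPchlide + chl_NADP + 2 chl_H2O	0 1000	tetrapyrrole	
chl_DVR	chl_DVPchlide + chl_NADPH -> chl_Pchlide + chl_NADP	0 1000	tetrapyrrole	
chl_POR	chl_Pchlide + chl_NADPH -> chl_Chlide + chl_NADP	0 1000	tetrapyrrole	OsPORA OR OsPORB
chl_CHLSYN	chl_Chlide + chl_PhyPP -> chl_Chla + chl_PPi	0 1000	tetrapyrrole	OsCHLG
chl_MEP_GGPP	4 chl_Pyr + 4 chl_GAP + 4 chl_ATP + 4 chl_NADPH -> chl_GGPP + 4 chl_CO2 + 4 chl_ADP + 4 chl_Pi + 4 chl_NADP + 3 chl_PPi	0 1000	isoprenoid	
chl_GGR	chl_GGPP + 3 chl_NADPH -> chl_PhyPP + 3 chl_NADP	0 1000	isoprenoid	OsCHLP
chlorophyll_tx	chl_Chla -> x_Chla	0 1000	demand	
chl_GS2	chl_Glu + chl_NH3 + chl_ATP -> chl_Gln + chl_ADP + chl_Pi	0 1000	nitrogen	OsGS2
cyt_GS1	cyt_Glu + cyt_NH3 + cyt_ATP -> cyt_Gln + cyt_ADP + cyt_Pi	0 1000	nitrogen	OsGS1;1 OR OsGS1;2
chl_GOGAT	chl_Gln + chl_2OG + chl_NADPH -> 2 chl_Glu + chl_NADP	0 1000	nitrogen	OsNADH-GOGAT
cyt_SHMT	cyt_Ser + cyt_THF <> cyt_Gly + cyt_MeTHF + cyt_H2O	-1000 1000	methyl_cycle	OsSHMT1
cyt_MTHFR	cyt_MeTHF + cyt_NADH -> cyt_5MeTHF + cyt_NAD	0 1000	methyl_cycle	OsMTHFR
cyt_MS	cyt_Hcy + cyt_5MeTHF -> cyt_Met + cyt_THF	0 1000	methyl_cycle	OsMS
cyt_SAMS	cyt_Met + cyt_ATP + cyt_H2O -> cyt_SAM + cyt_PPi + cyt_Pi	0 1000	methyl_cycle	OsSAMS1 OR OsSAMS2
cyt_SAHH	cyt_AdoHcy + cyt_H2O -> cyt_Hcy + cyt_Adenosine	0 1000	methyl_cycle	OsSAHH
cyt_ADNSALV	cyt_Adenosine + cyt_ATP -> cyt_ADP + cyt_AMP	0 1000	methyl_cycle	
cyt_ADK	cyt_AMP + cyt_ATP -> 2 cyt_ADP	0 1000	housekeeping	
cyt_PPase	cyt_PPi + cyt_H2O -> 2 cyt_Pi	0 1000	housekeeping	
cyt_PGADH	cyt_PGA + cyt_NAD -> cyt_PHP + cyt_NADH	0 1000	serine	
cyt_PSAT	cyt_PHP + cyt_Glu -> cyt_PSer + cyt_2OG	0 1000	serine	
cyt_PSP	cyt_PSer + cyt_H2O -> cyt_Ser + cyt_Pi	0 1000	serine	
cyt_PDH	cyt_Pyr + cyt_CoA + cyt_NAD -> cyt_AcCoA + cyt_CO2 + cyt_NADH	0 1000	carbon	
cyt_CS	cyt_OAA + cyt_AcCoA + cyt_H2O -> cyt_CIT + cyt_CoA	0 1000	carbon	
cyt_MDH	cyt_OAA + cyt_NADH <> cyt_Mal + cyt_NAD	-1000 1000	carbon	
cyt_NDex	cyt_NADH + 0.5 cyt_O2 -> cyt_NAD + cyt_H2O	0 1000	respiration	
mit_ACON	mit_CIT <> mit_ICIT	-1000 1000	tca	OsACO
mit_ICDH	mit_ICIT + mit_NAD -> mit_2OG + mit_CO2 + mit_NADH	0 1000	tca	OsICDH
mit_GDC	mit_Gly + mit_THF + mit_NAD -> mit_MeTHF + mit_NH3 + mit_CO2 + mit_NADH	0 1000	photorespiration	OsGLDC AND OsGCSH
mit_SHMT	mit_MeTHF + mit_Gly + mit_H2O -> mit_Ser + mit_THF	0 1000	photorespiration	OsSHMT2
mit_ETC	mit_NADH + 0.5 mit_O2 + 2.5 mit_ADP + 2.5 mit_Pi -> mit_NAD + 2.5 mit_ATP + 3.5 mit_H2O	0 1000	respiration	
mit_AOX	mit_NADH + 0.5 mit_O2 -> mit_NAD + mit_H2O	0 1000	respiration	
per_GOX	per_Glycolate + per_O2 -> per_Glyoxylate + per_H2O2	0 1000	photorespiration	OsGLO
per_CAT	per_H2O2 -> per_H2O + 0.5 per_O2	0 1000	photorespiration	OsCATA
per_SGAT_HPR	per_Ser + per_Glyoxylate + per_NADH -> per_Gly + per_Glycerate + per_NAD	0 1000	photorespiration	
per_GGAT	per_Glu + per_Glyoxylate -> per_Gly + per_2OG	0 1000	photorespiration	
per_MDH	per_Mal + per_NAD -> per_OAA + per_NADH	0 1000	photorespiration	
chl_PGP	chl_PGlyc + chl_H2O -> chl_Glycolate + chl_Pi	0 1000	photorespiration	
chl_GLYK	chl_Glycerate + chl_ATP -> chl_PGA + chl_ADP	0 1000	photorespiration	
Mal_2OG_chl_tx	cyt_2OG + chl_Mal -> chl_2OG + cyt_Mal	0 1000	shuttle	
Mal_Glu_chl_tx	chl_Glu + cyt_Mal -> cyt_Glu + chl_Mal	0 1000	shuttle	
Mal_OAA_chl_tx	chl_OAA + cyt_Mal <> cyt_OAA + chl_Mal	-1000 1000	shuttle	
Glu_Gln_chl_tx	cyt_Gln + chl_Glu -> chl_Gln + cyt_Glu	0 1000	shuttle	
SAM_tx_T1	cyt_SAM -> chl_SAM	0 1000	shuttle	
AdoHcy_tx_T2	chl_AdoHcy -> cyt_AdoHcy	0 1000	shuttle	
PGA_chl_tx	chl_PGA -> cyt_PGA	0 1000	shuttle	
Pyr_chl_tx	chl_Pyr -> cyt_Pyr	0 1000	shuttle	
CO2_chl_tx	cyt_CO2 <> chl_CO2	-1000 1000	gas	
O2_chl_tx	chl_O2 <> cyt_O2	-1000 1000	gas	
H2O_chl_tx	cyt_H2O <> chl_H2O	-1000 1000	gas	
Pi_chl_tx	cyt_Pi <> chl_Pi	-1000 1000	shuttle	
Glycolate_chl_per_tx	chl_Glycolate -> per_Glycolate	0 1000	photorespiration	
Glycerate_per_chl_tx	per_Glycerate -> chl_Glycerate	0 1000	photorespiration	
NH_3__tx	x_NH3 -> cyt_NH3	0 1000	nitrogen	
ex_ammonia_tx	x_NH3 -> chl_NH3	0 1000	nitrogen	
NH3_chl_cyt_diff	chl_NH3 -> cyt_NH3	0 0	nitrogen	
NH3_mit_chl_tx	mit_NH3 -> chl_NH3	0 1000	nitrogen	
CIT_mit_tx	cyt_CIT -> mit_CIT	0 1000	shuttle	
OG_mit_tx	mit_2OG -> cyt_2OG	0 1000	shuttle	
Gly_mit_tx	cyt_Gly -> mit_Gly	0 1000	shuttle	
Ser_mit_tx	mit_Ser -> cyt_Ser	0 1000	shuttle	
CO2_mit_tx	mit_CO2 <> cyt_CO2	-1000 1000	gas	
O2_mit_tx	cyt_O2 <> mit_O2	-1000 1000	gas	
H2O_mit_tx	cyt_H2O <> mit_H2O	-1000 1000	gas	
Pi_mit_tx	cyt_Pi <> mit_Pi	-1000 1000	shuttle	
ANT_mit_tx	mit_ATP + cyt_ADP -> cyt_ATP + mit_ADP	0 1000	shuttle	
Ser_per_tx	cyt_Ser -> per_Ser	0 1000	photorespiration	
Gly_per_tx	per_Gly -> cyt_Gly	0 1000	photorespiration	
Glu_per_tx	cyt_Glu -> per_Glu	0 1000	photorespiration	
OG_per_tx	per_2OG -> cyt_2OG	0 1000	photorespiration	
Mal_per_tx	cyt_Mal -> per_Mal	0 1000	photorespiration	
OAA_per_tx	per_OAA -> cyt_OAA	0 1000	photorespiration	
O2_per_tx	cyt_O2 <> per_O2	-1000 1000	gas	
H2O_per_tx	cyt_H2O <> per_H2O	-1000 1000	gas	
CO2_tx	x_CO2 <> cyt_CO2	-1000 1000	exchange	
O2_tx	cyt_O2 <> x_O2	-1000 1000	exchange	
H2O_tx	x_H2O <> cyt_H2O	-1000 1000	exchange	
Pi_tx	x_Pi <> cyt_Pi	-1000 1000	exchange	
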