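# Conserved CYP motif occurrence/position survey for the moon jellyfish (Aaur) CYPome,
# transcribed from the published annotation tables. Positions are 1-based starts;
# '-' marks a motif the survey reports as absent. Status left blank where the
# published per-gene status is not derivable.
# Row CYP3341A4 omitted: the published heme-loop position (255) exceeds the
# published protein length (228), an internal inconsistency of the source table.
gene_name	species	length	ihelix_pos	ihelix_str	khelix_pos	khelix_str	meander_pos	meander_str	heme_pos	heme_str	status
CYP4KY1	Aaur	525	332	EGHDTT	390	ESLR	443	FIPER	464	FSAGPRNCVG	
CYP20A1	Aaur	481	-	-	348	ETLR	400	FDPER	423	F-AGKRKCPG	
CYP375E1	Aaur	440	248	AGVDTT	305	ETLR	357	FKPER	380	FGFGVRMCLG	
CYP375E2	Aaur	440	248	AGVDTT	305	ETLR	357	FKPER	380	FGFGVRMCLG	
CYP3336A1	Aaur	502	310	AGHHTS	367	EAMR	419	YNPDR	441	FARGPRMCIG	
CYP3336B1	Aaur	504	309	AGHETT	366	ESMR	418	FNPDR	442	FSRGPRMCIG	
CYP3336B2	Aaur	332	143	AGSTSL	196	ESMR	248	FNPDR	270	FSRGPRMCIG	
CYP3336B3	Aaur	323	134	AGSTSL	187	ESMR	239	FNPDR	261	FSRGPRMCIG	
CYP3337A1	Aaur	474	315	AGFETT	372	ESLR	424	FDPER	447	FSNGPRNCIG	
CYP3338A1	Aaur	521	330	AAVDTT	387	ESMR	439	FKPKR	462	FGYGVRMCLG	
CYP3341A1	Aaur	501	309	AGYDTS	366	ETLR	418	FKPER	439	FGAGPRNCIG	
CYP3341A2	Aaur	501	309	AGYDTS	366	ETLR	418	FKPER	439	FGAGPRNCIG	
CYP3341A3	Aaur	502	309	AGYEST	366	ETLR	418	FKPER	439	FGMGPRNCIG	
CYP3341A5	Aaur	225	34	AGYDTS	93	ETLR	139	FPDPE	166	FGMGPRNCIG	
CYP3341A6	Aaur	227	34	AGYEST	91	ETLR	143	FKPER	164	FGMGPRNCIG	
CYP3341A7	Aaur	226	34	AGYDTS	91	ETLR	137	FPDPE	164	FGMGPRNCIG	
CYP3341A8	Aaur	226	34	VGYDTS	91	ETLR	143	FKPER	164	FGMGPRNCIG	
CYP3350A1	Aaur	499	302	AGSDTT	358	EVLR	411	FQPER	433	FSAGKRICLG	
CYP3350B1	Aaur	498	305	TGTETT	360	EVLR	413	FAPER	435	FSVGKRVCLG	
CYP3350B2	Aaur	220	27	TGTETT	82	EVLR	135	FAPER	157	FSVGKRVCLG	
CYP3351A1	Aaur	316	122	AGVDTT	179	ETLR	231	FMPER	254	FSIGRRRCPG	
CYP3351A2	Aaur	469	275	AGVDTT	332	ETLR	384	FMPER	407	FSIGRRRCPG	
CYP3352E1	Aaur	499	302	AGSETT	359	ETLR	412	FIPER	435	FSAGRRVCLG	
CYP3352E2	Aaur	499	302	AGSETT	359	ETLR	412	FIPER	435	FSAGRRVCLG	
CYP3352F1	Aaur	495	302	AGAETT	358	ETLR	411	FRPER	434	FGAGRRVCVG	
CYP3352F2	Aaur	495	302	GGAETT	358	ETLR	411	FRPER	434	FGAGRRVCLG	
CYP3352F3	Aaur	487	291	AGSETT	347	EIFR	399	FKPER	422	FGAGRRGCLG	
CYP3352F4	Aaur	503	302	SGAETT	358	ETLR	411	FKPER	434	FGAGRRVCIG	
CYP3352F5	Aaur	328	127	SGAETT	183	ETLR	236	FKPER	259	FGAGRRVCIG	
CYP3552G1	Aaur	506	300	AGSETT	357	EVLR	410	FNPER	433	FSAGRRVCLA	
CYP3352H1	Aaur	498	303	AAIDTT	360	ETLR	413	FKPER	436	FSAGKRVCFG	
CYP3352H2	Aaur	322	127	AAIETT	184	ETAR	237	FQPER	260	FSAGKRVCFG	
CYP3352H3	Aaur	498	303	AAIETT	360	ETAR	413	FQPER	436	FSAGKRVCFG	
CYP3352H4	Aaur	498	303	AATETT	360	ESAR	413	FQPER	436	FSAGKRVCFG	
CYP3352H5	Aaur	322	127	AATETT	184	ESAR	237	FQPER	260	FSAGKRVCFG	
CYP3352H6	Aaur	498	303	AAIETT	360	ETAR	413	FQPER	436	FSAGKRVCFG	
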