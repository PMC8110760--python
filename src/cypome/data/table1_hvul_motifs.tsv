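# Conserved CYP motif occurrence/position survey for the brown hydra (Hvul) CYPome,
# transcribed from the published annotation tables. Positions are 1-based starts;
# '-' marks a motif the survey reports as absent. Status left blank where the
# published per-gene status is not derivable.
gene_name	species	length	ihelix_pos	ihelix_str	khelix_pos	khelix_str	meander_pos	meander_str	heme_pos	heme_str	status
CYP4LA1	Hvul	491	302	EGHDTT	358	ESLR	410	FIPER	431	FSAGPRNCIG	
CYP4LA2	Hvul	502	300	AGHDTI	356	ESMR	408	FIPER	429	FSAGSRNCLG	
CYP4LA3	Hvul	497	308	EGHDTT	364	ESLR	416	FIPER	437	FSAGPRNCIG	
CYP4LA4	Hvul	498	309	EGHDST	365	ESMR	417	FIPER	438	FSAGPRNCIG	
CYP4LA5	Hvul	505	316	EGHDTT	372	ESLR	424	FIPER	424	FSAGPRNCIG	
CYP4LB1	Hvul	506	291	AGHDTT	349	ESLR	401	FIPER	422	FSAGPRNCIG	
CYP20A1	Hvul	496	-	-	360	EVMR	412	FDPDR	433	FGFAGKRKCPG	
CYP3352A1	Hvul	497	297	AGSETS	354	ETLR	407	FYPER	430	FSSGPRSCIG	
CYP3352A2	Hvul	447	303	AGSETS	360	ETLR	413	FYPER	436	FSSGPRSCLG	
CYP3352A3	Hvul	493	298	AGSETS	355	ETLR	408	FYPER	431	FSNGPRSCLG	
CYP3352A4	Hvul	493	298	AGSETS	355	ETLR	408	FYPER	431	FSGGPRACLG	
CYP3352A5	Hvul	326	131	AGSETS	188	ETLR	241	FYPER	264	FSSGPRSCLG	
CYP3352A6	Hvul	322	127	AGSETS	184	ETLR	237	FYPER	260	FSGGPRSCLG	
CYP3352A7	Hvul	308	129	AGSETS	169	ETLR	222	FYPER	245	FSGGPRSCLG	
CYP3352B1	Hvul	505	300	SGSETT	357	ETLR	410	FNPYR	433	FSTGLRACLG	
CYP3352C1	Hvul	506	300	AGTETA	357	ETLR	411	FNPYR	434	FSAGTRVCLG	
CYP3352C2	Hvul	518	300	AGTETA	357	ETLR	357	FNPYR	434	FSAGTRVCLG	
CYP3352D1	Hvul	506	300	GGVETT	357	ESLR	410	FNPYR	433	FSIGLRACLG	
CYP3352D2	Hvul	507	260	AGSETT	317	ECLR	370	FNPHR	393	FSAGTRVCLG	
CYP3352D3	Hvul	499	276	TGSETT	333	ECLR	386	FNPYR	409	FSAGTRVCLG	
CYP3352D4	Hvul	475	276	TGSETT	333	ECLR	386	FNPYR	409	FSAGTRVCLG	
CYP3352D5	Hvul	444	300	GGSETT	357	ECLR	410	FNPYR	433	FSAGTRVCLG	
CYP3353A1	Hvul	489	295	AGSETT	351	ETLR	404	FNPMR	427	FSAGPRGCIG	
CYP3354A1	Hvul	499	299	AGTETT	355	ETLR	408	FDPKR	431	FSAGARVCLG	
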