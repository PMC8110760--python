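# Conserved CYP motif occurrence/position survey for the stony coral (Adig) CYPome,
# transcribed from the published annotation tables. Positions are 1-based starts;
# '-' marks a motif the survey reports as absent. Status left blank where the
# published per-gene status is not derivable.
gene_name	species	length	ihelix_pos	ihelix_str	khelix_pos	khelix_str	meander_pos	meander_str	heme_pos	heme_str	status
CYP375B3	Adig	504	303	AGVDTT	360	ETLR	412	FKPER	439	FGFGTRMCLG	
CYP3094B1	Adig	504	309	AGLETS	366	EVLR	419	FNPER	442	FGAGRRGCLG	
CYP3094H1	Adig	440	284	AGSETL	342	EALR	395	FDPNR	418	FSAGRRVCLG	
CYP3094J1	Adig	485	290	AGLETT	347	EVLR	400	FDPSR	423	FGAGRRVCLG	
CYP3094K1	Adig	451	280	AGSDIT	337	EIMR	390	FDPTR	414	FGGGLRACMG	
CYP3094K2	Adig	451	280	AGSDIT	337	EIMR	390	FDPTR	414	FGGGLRACMG	
CYP3339A1	Adig	516	311	AGYETS	369	EALR	421	FDPER	442	FGSGPRVCIG	
CYP3339A2	Adig	462	267	AGYETS	326	ESQR	378	FDPER	399	FGAGPRNCIG	
CYP3339A3	Adig	511	317	AGYETS	376	EALR	428	FDPER	449	FGAGPRNCIG	
CYP3339A4	Adig	493	299	AGYETS	358	ETLR	410	FDPER	431	FGAGPRNCIG	
CYP3342A5	Adig	228	36	AGYETS	94	ETLR	146	FDPER	167	FGHGPHNCVG	
CYP3343A1	Adig	481	291	GGYEKL	347	EILR	400	FNPYR	422	FSTGDRKCPG	
CYP3344A1	Adig	489	291	AGIDTV	348	ETLR	401	FNPHR	424	FSTGGRRCLG	
CYP3346A1	Adig	489	290	AGFETS	347	ELLR	400	FNPRR	424	FSGGRRKCPG	
CYP3346A2	Adig	476	276	GGAIDTS	334	ELLR	387	FNPRR	411	FSVGRRQCPG	
CYP3346A3	Adig	476	276	GGAIDTS	334	ELLR	387	FNPRR	411	FSVGRRQCPG	
CYP3346A4	Adig	492	293	AGFDTS	350	ELLR	403	FCPSR	427	FSAGRRKCPG	
CYP3346A5	Adig	359	160	AGFETS	217	ELLR	270	FNPKR	294	FSGGRRKCPG	
CYP3346A6	Adig	491	313	AGFETS	370	ELLR	423	FYPRR	447	FSGGRRKCPG	
CYP3348A1	Adig	397	206	AGYETT	262	ESLR	315	FNPYR	337	FGAGRRVCAG	
CYP3348A2	Adig	403	207	AGYETT	263	ESLR	316	FNPYR	338	FGAGRRVCAG	
CYP3348B6	Adig	346	197	AGYETT	254	EALR	307	FNPQR	329	FSAGRRVCAG	
CYP3348B7	Adig	348	197	AGYETT	254	EALR	307	FNPHR	329	FSAGRRVCAG	
CYP3355C1	Adig	495	298	AGMETT	355	ETLR	408	FRPDR	431	FSGGRRSCLG	
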