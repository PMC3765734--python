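row_id	gene_id	seq_id	published_pattern	embryo_a	embryo_b	larva_a	larva_b	pupa_a	pupa_b	adult_a	adult_b	annotation
S1	P35035	HARM050658	S	74	71	0	0	0	0	0	0	Trypsin-1
S2	Q35826	HARM066614	S	234233	174746	185711	167262	159977	163095	132374	81008	Cytochrome c oxidase polypeptide III
D1	Q9VYY4	HARM012503	D	41	52	5	337	34	137	13	46	Cytochrome P450 4 g15
D2	P54191	HARM016746	D	7	8	0	19	2	2	0	0	Pheromone-binding protein-related protein 1
D3	AEB54582	HARM004409	D	185	17	63	785	357	79	158	0	OBP3
D4	Q00871	HARM066585	D	0	0	5	1524	340	1511	0	0	Chymotrypsin BI
D5	P46441	HARM051295	D	187	0	77	2	64	0	41	0	Putative ATPase N2B
D6	Q9VGG8	HARM002903	D	0	23	7	0	0	2	3	3	Probable G-protein coupled receptor Mth-like 5
D7	Q11001	HARM001041	D	8	9	0	104	16	52	3	71	Membrane alanyl aminopeptidase
D8	Q964T2	HARM001432	D	4	4	0	15	15	15	0	3	Cytochrome P450 9e2
D9	Q9QYZ9	HARM001863	D	0	0	2	128	20	158	0	10	Serine protease 30
D10	Q0II73	HARM066611	D	0	0	4	1079	53	315	0	0	Carboxypeptidase O
D11	P62333	HARM025783	D	37	47	9	138	0	199	12	239	26S protease regulatory subunit 10B
D12	O18598	HARM027201	D	23	4	156	92	222	2	45	0	Glutathione S-transferase
D13	Q9V675	HARM053132	D	89	2	36	13	46	13	273	0	Probable cytochrome P450 6 g2
D14	Q9V7G5	HARM039905	D	0	0	8	241	81	39	0	670	Probable cytochrome P450 4aa1
D15	P46430	HARM034436	D	0	56	0	0	8	222	2	0	Glutathione S-transferase 1
D16	ACV60230	HARM024407	D	2	0	0	23	8	9	0	2	antennal esterase CXE3
D17	Q27377	HARM028696	D	21	0	267	5	11	3	0	0	Putative odorant-binding protein A10
D18	AEX07273	HARM051397	D	111	3	0	0	73	4	2	0	odorant-binding protein
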