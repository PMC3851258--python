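pathway_id	pathway_name	low	mid	high	genes
eco03010	Ribosome	0.32	0.40	0.45	rplN, rplY, rpmB, rpsB, rpsJ, rpsL, rpsM, rpsO, rpsP, rpsT, rpsU, rrnA, rrnB, rrnC, rrnD, rrnH
eco01100	Metabolic pathways	0.45	0.42	0.69	aceB, acnB, aspA, gatY, ilvC, lpxC, manX, ribB, rpiA, serC
eco01120	Microbial metabolism in diverse environments	0.59	0.45	0.78	aceB, acnB, manX, rpiA, serC
eco01230	Biosynthesis of amino acids	0.55	0.38	0.95	acnB, ilvC, rpiA, serC
eco01110	Biosynthesis of secondary metabolites	0.55	0.63	0.95	acnB, ilvC, rpiA, yfbE
eco00520	Amino sugar and nucleotide sugar metabolism	0.61	0.52	0.79	manX, ptsG, yfbE
eco01210	2-Oxocarboxylic acid metabolism	0.10	0.25	1.00	acnB, ilvC
eco00970	Aminoacyl-tRNA biosynthesis	0.71	0.67	1.00	ileX, tyrS
eco00564	Glycerophospholipid metabolism	0.39	0.37	0.76	glpA, glpD
eco00630	Glyoxylate and dicarboxylate metabolism	0.30	0.49	0.79	aceB, acnB
eco00910	Nitrogen metabolism	0.68	0.73	0.80	aspA, yadF
eco02060	Phosphotransferase system (PTS)	0.41	0.37	0.62	ptsG, treB
eco02010	ABC transporters	0.48	0.50	0.67	oppA
eco00020	Citrate cycle (TCA cycle)	0.20	0.50	1.00	acnB
eco00051	Fructose and mannose metabolism	0.33	0.24	0.52	manX
eco00010	Glycolysis/Gluconeogenesis	0.50	0.33	0.83	ptsG
eco00540	Lipopolysaccharide biosynthesis	0.17	0.38	0.73	lpxC
eco00190	Oxidative phosphorylation	0.00	0.00	1.00	ppa
eco00770	Pantothenate and CoA biosynthesis	0.00	0.00	1.00	ilvC
eco00640	Propanoate metabolism	0.20	0.50	1.00	acnB
eco00620	Pyruvate metabolism	0.41	0.49	0.59	aceB
eco00290	Valine, leucine and isoleucine biosynthesis	0.00	0.00	1.00	ilvC
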