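component	ion	mmol_per_mmol
arginine	Cl-	1.0
lysine	Cl-	1.0
histidine	Cl-	1.0
ornithine	Cl-	1.0
citrulline	Cl-	0.0
choline	Cl-	1.0
ethanolamine	Cl-	1.0
putrescine	Cl-	2.0
spermidine	Cl-	3.0
lactate	Na+	1.0
pyruvate	Na+	1.0
acetate	Na+	1.0
formate	Na+	1.0
propionate	Na+	1.0
butyrate	Na+	1.0
citrate	Na+	3.0
succinate	Na+	2.0
malate	Na+	2.0
fumarate	Na+	2.0
alpha-ketoglutarate	Na+	2.0
3-hydroxybutyrate	Na+	1.0
urate	Na+	1.0
orotate	Na+	1.0
gluconate	Na+	1.0
glucuronate	Na+	1.0
ascorbate	Na+	1.0
folate	Na+	2.0
pantothenate	Ca2+	0.5
glutamate	Na+	1.0
aspartate	Na+	1.0
taurocholate	Na+	1.0
glycocholate	Na+	1.0
alpha-glycerophosphate	Na+	2.0
alpha-glycerophosphate	phosphate	1.0
phosphocholine	phosphate	1.0
phosphoethanolamine	phosphate	1.0
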