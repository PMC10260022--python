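name	target_uM	pool_id
alanine	620	1
arginine	2.0	2
asparagine	120	3
aspartate	55	4
cystine	30	5
glutamate	140	6
glutamine	310	7
glycine	480	8
histidine	75	9
isoleucine	95	10
leucine	160	1
lysine	260	2
methionine	48	3
phenylalanine	85	4
proline	210	5
serine	170	6
threonine	190	7
tryptophan	55	8
tyrosine	80	9
valine	230	10
citrulline	67.0	1
ornithine	45	2
taurine	380	3
hypotaurine	12	4
creatine	150	5
creatinine	35	6
carnitine	42	7
acetylcarnitine	14	8
betaine	60	9
choline	28	10
sarcosine	4.2	1
dimethylglycine	7.5	2
1-methylhistidine	6.8	3
3-methylhistidine	3.1	4
hydroxyproline	38	5
homoserine	2.4	6
cystathionine	1.8	7
alpha-aminobutyrate	18	8
beta-alanine	9.5	9
N-acetylglycine	2.2	10
guanidinoacetate	11	1
kynurenine	3.6	2
urea	6400	3
putrescine	1.2	4
spermidine	1.4	5
glucose	1900	6
fructose	55	7
galactose	28	8
mannose	42	9
ribose	18	10
lactate	7400	1
pyruvate	62	2
citrate	160	3
succinate	38	4
malate	24	5
fumarate	9.0	6
alpha-ketoglutarate	12	7
3-hydroxybutyrate	130	8
glycerol	240	9
myo-inositol	85	10
glucosamine	7.2	1
N-acetylglucosamine	16	2
gluconate	21	3
glucuronate	4.8	4
sorbitol	13	5
hypoxanthine	22	6
xanthine	8.4	7
uracil	6.1	8
uridine	14	9
inosine	4.4	10
adenosine	1.1	1
guanosine	1.6	2
cytidine	3.8	3
thymidine	1.9	4
adenine	1.3	5
orotate	2.6	6
urate	120	7
allantoin	46	8
pseudouridine	5.2	9
2-deoxyuridine	0.9	10
niacinamide	9.8	1
nicotinate	2.1	2
pantothenate	5.6	3
pyridoxine	1.0	4
pyridoxal	1.7	5
riboflavin	0.8	6
thiamine	1.2	7
biotin	0.6	8
folate	0.7	9
4-aminobenzoate	0.9	10
ascorbate	48	1
formate	95	2
acetate	310	3
propionate	12	4
butyrate	5.5	5
2-hydroxybutyrate	34	6
3-hydroxyisobutyrate	19	7
2-hydroxyglutarate	6.3	8
itaconate	2.8	9
glycolate	25	10
malonate	3.4	1
glycerophosphocholine	26	2
phosphocholine	8.9	3
ethanolamine	16	4
phosphoethanolamine	4.1	5
hippurate	7.7	6
phenyllactate	3.2	7
4-hydroxyphenyllactate	5.9	8
indole-3-propionate	1.1	9
anthranilate	0.8	10
alpha-glycerophosphate	15	1
taurocholate	2.3	2
glycocholate	1.5	3
trimethylamine-N-oxide	24	4
dimethylsulfone	5.1	5
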