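ion	mM
Na+	138.0
K+	5.3
Cl-	108.0
Ca2+	0.42
Mg2+	0.41
phosphate	5.6
sulfate	0.41
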