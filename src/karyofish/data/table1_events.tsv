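# Chromosomal structure variation across the 11 materials (transcribed
# presence/absence grid). Cells: + present, - absent, 0 the species lacks
# that subgenome. Trailing quote marks preserve the source superscripts
# (' species-specific claim, '' possibly ancestral); they are stripped by
# the reader into an annotation grid used only for cross-checks and play
# no role in classification.
chrom	label	Hbw:H_bogdanii	DY:E_sibiricus	GEM:E_sibiricus	KB:E_sibiricus	XN:E_sibiricus	NM:E_sibiricus	LJS:E_sibiricus	PJC:E_nutans	B05:E_nutans	H11:E_nutans	G04:E_nutans
1H	PeI I	+'	+'	+'	+'	+'	+'	+'	+''	+''	+''	+''
1H	PeI II	-	-	-	-	-	-	-	+'	+'	+'	+'
1St	RT (5H/1St)	0	-	-	+	-	-	-	-	-	-	-
1St	De (1H514)	0	-	-	-	-	-	-	+	-	-	-
1Y	Du (2H558)	-	-	-	-	-	-	-	-	-	-	+
2H	PaI I	+	-	-	-	-	-	-	-	-	-	-
2H	PeI I	+''	+'	+'	+'	+'	+'	+'	+''	+''	+''	+''
2H	PeI II	-	-	-	-	-	-	-	+'	+'	+'	+'
2H	RT (2H/2St)	-	-	-	-	-	-	+	-	-	-	-
2St	PeI I	0	+'	+'	+'	+'	+'	+'	-	-	-	-
2St	RT (2H/2St)	0	-	-	-	-	-	+	-	-	-	-
2St	RT (4H/2St)	0	-	-	-	-	-	-	-	-	-	+
2Y	PeI III	0	0	0	0	0	0	0	+'	+'	+'	+'
3H	Du (3H448)	-	-	-	-	-	-	-	+	+	-	+
3H	T (4H)	+	-	-	-	-	-	-	-	-	-	-
3H	RT (3H/6H)	-	-	-	-	-	-	-	-	+	-	-
3H	PeI	-	+'	+'	+'	+'	+'	+'	-	-	-	-
3St	Du (3H448)	-	-	-	-	-	-	-	-	+	+	+
3Y	De (3H287)	0	0	0	0	0	0	0	+	-	+	-
3Y	PaI, RT (4H/3Y)	0	0	0	0	0	0	0	-	-	+	-
4H	Du (2L-1)	-	-	-	-	-	-	-	-	+	-	+
4H	PeI I	+	-	-	-	-	-	-	+	-	-	-
4H	PeI II	-	+''	+''	+''	+''	+''	+''	-	-	-	-
4H	PeI III	-	-	-	-	+	-	-	-	-	-	-
4H	PeI IV	-	+	+	+	-	+	+	-	-	-	-
4H	PeI V	-	-	-	-	-	-	-	-	-	-	+
4H	PaI I	-	-	-	-	-	-	-	+''	+''	+''	+''
4H	RT (4H/6H)	-	+'	+'	+'	+'	+'	+'	-	-	-	-
4H	RT (4H/3Y)	-	-	-	-	-	-	-	-	-	+	-
4H	RT (4H/2St)	-	-	-	-	-	-	-	-	-	-	+
4H	T (4H)	+	-	-	-	-	-	-	-	-	-	-
4St	PaI II	0	+'	+'	+'	+'	+'	+'	-	-	-	-
4Y	PeI VI, PeI VII, RT (4Y/5Y)	0	0	0	0	0	0	0	+'	+'	+'	+'
5H	Du (1H514)	+	-	-	-	-	-	-	-	-	-	-
5H	PaI I, II	+	-	-	-	-	-	-	-	-	-	-
5H	RT (5H/1St)	-	-	-	+	-	-	-	-	-	-	-
5St	PeI I	0	+'	+'	+'	+'	+'	+'	-	-	-	-
5Y	PeI I, RT (4Y/5Y)	0	0	0	0	0	0	0	+'	+'	+'	+'
5Y	PeI II	0	0	0	0	0	0	0	-	-	+	-
6H	PeI	-	+'	+'	+'	+'	+'	+'	+	-	+	-
6H	RT (4H/6H)	-	+'	+'	+'	+'	+'	+'	-	-	-	-
6H	RT (3H/6H)	-	-	-	-	-	-	-	-	+	-	-
7H	PaI	-	-	-	-	-	-	-	-	+	-	+
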