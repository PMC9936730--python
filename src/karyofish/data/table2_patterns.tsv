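# Repeat-FISH pattern codes per material x chromosome (transcribed
# material rows). The same letter within a column marks the same repeat
# pattern; a trailing apostrophe flags a variant carrying an additional
# polymorphic rearrangement; - marks subgenomes the species lacks.
# The printed per-column summary rows are NOT transcribed here: variant
# counting must recompute them.
material	species	1H	2H	3H	4H	5H	6H	7H	1St	2St	3St	4St	5St	6St	7St	1Y	2Y	3Y	4Y	5Y	6Y	7Y
DY	E_sibiricus	a	a	a	a	a	a	a	a	a	a	a	a	a	a	-	-	-	-	-	-	-
GEM	E_sibiricus	b	a	a	a	a	a	b	a	a	a	a	a	a	a	-	-	-	-	-	-	-
KB	E_sibiricus	a	b	a	b	b'	a	a	b'	a	a	a	b	a	a	-	-	-	-	-	-	-
XN	E_sibiricus	c	c	a	a'	a	a	c	a	b	a	a	c	a	a	-	-	-	-	-	-	-
NM	E_sibiricus	c	c	a	c	a	a	a	a	c	a	a	c	a	a	-	-	-	-	-	-	-
LJS	E_sibiricus	d	d'	a	c	a	a	b	a	d'	a	a	c	a	a	-	-	-	-	-	-	-
PJC	E_nutans	a	a	a'	a'	a	a'	a	a'	a	a	a	a	a	a	a	a	a'	a	a	a	a
B05	E_nutans	a	b	b'	b'	a	b'	b'	b	b	a'	b	b	a	b	b	b	b	b	b	b	b
H11	E_nutans	b	c	a	c'	a	a'	a	a	c	a'	c	a	b	c	b	c	c'	c	c'	c	c
G04	E_nutans	b	d	c'	d'	a	c	b'	a	d'	b'	b	a	c	a	a'	b	d	b	d	d	d
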