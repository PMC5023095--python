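sample	M175	RPS4Y	M231	M174	M304	M242	M207	M173	M17	M343
MN0104	TTCTC	C	G	T	T	C	G	C	G	A
MN0126	TTCTC	-	-	-	T	C	G	-	-	A
MN0376	TTCTC	C	G	T	T	C	G	C	G del	ND
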