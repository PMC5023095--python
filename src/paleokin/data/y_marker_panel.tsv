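marker	haplogroup	parent	mutation	ancestral	derived
M175	O	root	del	TTCTC	del
RPS4Y	C	root	sub	C	T
M231	N	root	sub	G	A
M174	D	root	sub	T	C
M304	J	root	sub	T	G
M242	Q	root	sub	C	T
M207	R	root	sub	A	G
M173	R1	R	sub	A	C
M17	R1a1a	R1	del	G	G del
M343	R1b	R1	sub	C	A
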