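label	parent	snps
reference	-	-
M	reference	10398G
CZ	M	4715G
M9	M	3394C
D	reference	5178A
D4	D	3010A
R	reference	10398C,12705C
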