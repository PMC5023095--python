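sample	group	lab	sex_anth	amel	hvr1	hvr2	coding	haplogroup
MN0104	body	1	male	XY	16171G 16223T 16311C 16362C	73G 263G 309+C 310+C	3010A,5178A	D4
MN0105	body	1	female	XX	16093C 16223T 16261T 16288C 16298C	73G 249del 263G 309+C 310+3C	10398G,4715G	CZ
MN0125	body	1	female	XX	16171G 16223T 16311C 16362C	73G 263G 309+C 310+C	3010A,5178A	D4
MN0126	body	1	male	XY	16171G 16223T 16311C 16362C	73G 263G 309+C 310+C	3010A,5178A	D4
MN0127	body	1	male	ND	16171G 16223T 16311C 16362C	73G 263G 309+C 310+C	3010A,5178A	D4
MN0124	body	1	female	XX	16217C	73G 152C 195C 263G 309+C 310+C	10398C,12705C	R
MN0376	body	1	male	XY	16223T 16234T 16299G 16362C	73G 146C 217C 263G 309+C 310+C	10398G,3394C	M9
MN0104	body	2	male	XY	16171G 16223T 16311C 16362C	73G 263G 309+C 310+C	3010A,5178A	D4
MN0105	body	2	female	XX	16093C 16223T 16261T 16288C 16298C	73G 249del 263G 309+C 310+3C	10398G,4715G	CZ
MN0125	body	2	female	XX	16171G 16223T 16311C 16362C	73G 263G 309+C 310+C	3010A,5178A	D4
MN0126	body	2	male	XY	16171G 16223T 16311C 16362C	73G 263G 309+C 310+C	3010A,5178A	D4
MN0127	body	2	male	ND	16171G 16223T 16311C 16362C	73G 263G 309+C 310+C	3010A,5178A	D4
MN0124	body	2	female	XX	16217C	73G 152C 195C 263G 309+C 310+C	10398C,12705C	R
MN0376	body	2	male	XY	16223T 16234T 16299G 16362C	73G 146C 217C 263G 309+C 310+C	10398G,3394C	M9
LabWorker1	researcher	-	-	XX	16223T 16362C	73G 195C 198T 263G 315+C	-	D4/G
LabWorker2	researcher	-	-	XX	16172C 16304C 16362C	73G 263G 309+C 315+C	-	R9b
Archaeologist1	researcher	-	-	XX	16092C 16129A 16223T 16266T 16271C	73G 263G 291T 309+C 310+C	-	-
Archaeologist2	researcher	-	-	XX	16189C 16223T 16257A 16261T 16269G	73G 150T 263G 309+C 310+C	-	-
Archaeologist3	researcher	-	-	XY	16092C 16129A 16223T 16271T 16262C	73G 150T 263G 290T 309+C 310+C	-	-
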