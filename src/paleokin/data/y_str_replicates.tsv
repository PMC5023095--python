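sample	replicate	DYS19	DYS385	DYS389I	DYS389II	DYS390	DYS391	DYS392	DYS393	DYS437	DYS438	DYS439	DYS448	DYS456	DYS458	DYS635	YGATAH4
MN0104	1	14	13/17	13	30	22	11	13	13	15	10	12	20	15	15	23	11
MN0104	2	14	13/17	13	30	22	11	13	13	15	10	12	20	15	15	23	11
MN0104	3	14	13/17	13	30	22	11	13	13	15	10	12	20	15	15	23	11
MN0126	1	14	13	-	-	-	11	-	13	-	-	12	-	-	15	23	11
MN0126	2	14	13	-	-	-	11	-	13	-	-	12	-	-	15	23	11
MN0126	3	14	13	-	-	-	11	-	13	-	-	12	-	-	15	23	11
MN0376	1	16	11/14	13	29	26	11	11	13	14	11	10	20	15	17	23	8/13
MN0376	2	16	11/14	13	29	26	11	11	13	14	11	10	20	15	17	23	13
MN0376	3	16	11/14	13	29	26	11	11	13	14	11	10	20	15	17	23	13
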