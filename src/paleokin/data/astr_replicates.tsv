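sample	replicate	lab	Amel	D13S317	D7S820	D2S1338	D21S11	D16S359	D18S51	CSF1PO	FGA
MN0104	1	1	XY	9/11	10/12	17/20	29/29	9/12	12/13	11/12	21/27
MN0104	2	1	XY	9/11	10/12	17/20	29/29	9/12	12/13	11/12	21/27
MN0104	3	2	XY	9/11	10/12	17/20	29/29	9/12	12/13	12/12	21/27
MN0105	1	1	XX	8/11	11/12	23/23	29/32.2	9/12	14/19	11/12	24/26
MN0105	2	1	XX	8/11	11/12	23/23	29/29	9/12	14/19	11/12	24/26
MN0105	3	2	XX	8/11	11/12	23/23	29/32.2	9/12	14/19	11/12	24/26
MN0125	1	1	XX	8/9	10/12	17/20	29/33.2	9/12	12/13	11/12	19/27
MN0125	2	1	XX	8/9	10/12	17/20	29/33.2	9/12	12/13	11/12	19/27
MN0125	3	2	XX	8/9	10/12	17/20	29/33.2	9/12	12/13	11/12	19/27
MN0126	1	1	XY	8/9	12/12	20/24	30/30	9/11	12/16	11/12	19/22
MN0126	2	1	-	-	-	-	-	-	-	-	-
MN0126	3	2	XY	8/9	12/12	20/24	30/33.2	9/11	12/16	11/12	19/22
MN0124	1	1	XX	11/12	8/8	17/23	29/30	9/12	13/13	12/13	23/24
MN0124	2	1	XX	11/12	8/8	17/23	29/30	9/9	13/16	12/13	23/24
MN0124	3	2	XX	11/12	8/8	17/23	29/30	9/12	13/16	12/13	23/24
MN0376	1	1	XY	12/12	10/10	23/27	31/32.2	9/9	13/24	9/12	21/23
MN0376	2	1	XY	12/12	10/10	23/27	31/32.2	9/9	13/24	9/12	21/23
MN0376	3	2	XY	12/12	10/10	23/27	31/32.2	9/9	13/24	9/12	21/23
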