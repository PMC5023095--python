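locus	allele	frequency
D13S317	8	0.12
D13S317	9	0.15
D13S317	10	0.08
D13S317	11	0.28
D13S317	12	0.27
D13S317	13	0.10
D7S820	8	0.15
D7S820	9	0.07
D7S820	10	0.20
D7S820	11	0.28
D7S820	12	0.22
D7S820	13	0.08
D2S1338	17	0.10
D2S1338	18	0.08
D2S1338	19	0.14
D2S1338	20	0.10
D2S1338	22	0.06
D2S1338	23	0.22
D2S1338	24	0.14
D2S1338	25	0.10
D2S1338	27	0.06
D21S11	28	0.06
D21S11	29	0.22
D21S11	30	0.26
D21S11	30.2	0.04
D21S11	31	0.10
D21S11	31.2	0.08
D21S11	32.2	0.12
D21S11	33.2	0.12
D16S359	9	0.25
D16S359	10	0.12
D16S359	11	0.25
D16S359	12	0.24
D16S359	13	0.14
D18S51	12	0.08
D18S51	13	0.20
D18S51	14	0.16
D18S51	15	0.16
D18S51	16	0.12
D18S51	17	0.08
D18S51	19	0.08
D18S51	20	0.04
D18S51	24	0.08
CSF1PO	9	0.06
CSF1PO	10	0.24
CSF1PO	11	0.26
CSF1PO	12	0.34
CSF1PO	13	0.10
FGA	19	0.08
FGA	20	0.06
FGA	21	0.12
FGA	22	0.18
FGA	23	0.20
FGA	24	0.14
FGA	25	0.06
FGA	26	0.08
FGA	27	0.08
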