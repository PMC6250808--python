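gene_id	degree_case	degree_control	kcore_case	kcore_control	dif_degree	dif_kcore
IFN-γ	0	41	0	27	-41	-27
IL26	0	38	0	26	-38	-26
TLR3	2	51	2	27	-49	-25
PRKCQ	2	37	2	26	-35	-24
IL17A	4	43	3	26	-39	-23
CDK1	10	53	7	27	-43	-20
TLR4	13	55	7	27	-42	-20
CD274	17	56	7	27	-39	-20
CXCL1	11	44	7	27	-33	-20
BRIP1	11	38	7	27	-27	-20
TNFSF10	1	26	1	21	-25	-20
CD209	9	45	7	26	-36	-19
RRM2	13	45	8	27	-32	-19
SOD2	14	55	9	27	-41	-18
FANCI	17	52	9	27	-35	-18
SELE	11	43	9	27	-32	-18
IL19	18	41	9	27	-23	-18
CCNB2	11	32	7	25	-21	-18
CYP7B1	12	57	10	27	-45	-17
CHEK1	11	52	10	27	-41	-17
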