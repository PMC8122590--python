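superfamily	family	S. clava	C. robusta	M. oculata	O. dioica	B. leachii	B. schlosseri	H. sapiens	B. floridae	C. elegans
	AF-4	1	1	1	1	1	1	8	1	0
	ARID	4	5	7	4	4	2	15	4	5
	BTD	2	2	2	2	2	3	6	2	1
bZIP	bZIP_1	13	16	12	21	15	7	37	14	11
bZIP	bZIP_2	6	7	7	8	6	2	12	8	17
	CBF_beta	1	1	1	1	1	1	1	1	1
NF-Y	CBFB_NFYA	1	1	0	1	1	0	1	1	2
NF-Y	CBFD_NFYB_HMF	8	9	8	13	8	4	45	16	9
	CG-1	0	1	1	0	0	0	2	1	1
	CP2	2	3	2	2	2	3	8	2	1
	CSD	9	5	4	7	4	4	17	2	5
	CSRNP_N	1	1	0	2	1	2	3	1	1
MH1	CTF_NFI	2	1	0	0	1	0	4	1	0
MH1	MH1	4	5	7	11	4	5	11	4	7
	E2F_TDP	2	4	4	3	3	2	20	4	5
ETS	Ets	12	15	12	11	14	12	29	12	10
ETS	ETS_PEA3_N	0	0	0	0	0	0	4	1	0
	Forkhead box	23	25	24	26	27	27	55	28	16
	GCFC	2	2	2	1	2	2	3	1	2
	GCM	0	0	0	0	0	0	2	1	0
	GTF2I	0	1	0	0	0	0	15	0	0
bHLH	bHLH	41	39	36	22	37	20	102	73	38
bHLH	Myc_N	0	1	1	0	0	1	4	1	0
bHLH	SIM_C	0	0	0	0	0	0	2	0	0
	HMG_box	20	20	14	19	18	21	102	29	16
Homeobox	Homeodomain	73	76	74	70	74	45	264	108	85
Homeobox	CUT	2	1	3	3	3	2	8	3	7
Homeobox	PBC	1	1	1	1	1	5	11	1	2
Homeobox	Pou	2	3	3	5	3	2	17	6	3
	HPD	2	2	1	1	1	1	3	0	1
	HSF_DNA-binding	1	1	0	4	1	2	9	5	1
	HTH_psq	6	2	3	0	9	0	2	5	1
IRF	IRF	5	5	6	2	8	5	3	4	0
IRF	IRF-3	1	3	2	0	4	9	9	4	0
	LAG1-DNAbinding	0	0	0	0	0	1	0	0	0
	LRRFIP	0	1	3	1	1	1	5	1	1
	MBD	3	2	4	0	3	2	7	3	2
	Myb_DNA-binding	12	13	11	7	13	11	25	16	7
	NCU-G1	1	0	1	0	1	2	1	1	0
	NDT80_PhoG	1	1	3	0	1	2	2	1	2
	Nrf1_DNA-binding	1	1	1	0	1	1	1	3	0
	P53	3	2	1	1	3	5	3	2	1
	PAX	7	6	5	8	5	2	9	5	9
	PC4	1	1	0	1	1	1	3	2	1
	RFX_DNA_binding	2	3	3	1	3	2	10	5	1
	RHD_DNA_binding	3	2	3	2	4	5	13	2	0
	Runt	1	1	1	1	1	2	3	1	1
	SAND	3	2	1	2	1	2	7	4	4
	SRF-TF	3	2	2	3	2	1	5	3	2
STAT	STAT_alpha	0	0	0	1	0	2	2	0	0
STAT	STAT_binding	2	2	2	2	2	2	5	1	2
STAT	STAT_int	0	1	0	0	0	0	0	2	0
	TAFH	2	1	1	1	1	1	6	3	1
	T-box	10	8	8	8	8	13	19	10	19
	TEA	1	1	1	2	1	1	4	1	1
	TF_AP-2	1	2	1	1	1	2	5	1	4
	TF_Otx	0	0	0	0	0	0	1	0	0
	TIG	11	7	6	12	16	29	18	15	4
	TSC22	2	1	1	0	2	1	4	1	5
	Tub	1	1	1	2	1	1	5	2	2
	Vert_HS_TF	0	0	0	0	0	0	3	0	0
zinc finger	THAP	21	8	27	0	40	49	9	7	3
zinc finger	GATA	5	4	4	5	5	2	17	7	12
zinc finger	DM	5	2	0	2	7	3	7	8	11
Nuclear Receptor	Hormone_receptor	6	6	6	7	5	9	28	10	151
Nuclear Receptor	Androgen_receptor	0	0	0	0	0	0	1	0	0
Nuclear Receptor	Oest_receptor	0	0	0	0	0	0	1	0	0
Nuclear Receptor	Prog_receptor	0	0	0	0	0	0	1	0	0
Nuclear Receptor	GCR	0	0	0	0	0	0	1	0	0
Nuclear Receptor	zf-C4	15	12	14	33	11	21	32	21	124
zinc finger	zf-BED	17	2	6	0	8	9	3	0	9
zinc finger	zf-C2H2	154	95	193	72	110	310	748	742	58
zinc finger	zf-C2HC	5	3	2	2	4	5	8	2	1
zinc finger	zf-LITAF-like	4	1	2	5	3	2	4	11	14
zinc finger	zf-MIZ	2	2	3	2	1	0	6	2	2
zinc finger	zf-NF-X1	1	1	2	0	1	1	1	1	1
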