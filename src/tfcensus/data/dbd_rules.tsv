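pfam_accession	family	superfamily	evalue_threshold
PF05110	AF-4		1e-4
PF01388	ARID		1e-4
PF09270	BTD		1e-4
PF00170	bZIP_1	bZIP	1e-4
PF07716	bZIP_2	bZIP	1e-4
PF02312	CBF_beta		1e-4
PF02045	CBFB_NFYA	NF-Y	1e-4
PF00808	CBFD_NFYB_HMF	NF-Y	1e-4
PF03859	CG-1		1e-4
PF04516	CP2		1e-4
PF00313	CSD		1e-4
PF16019	CSRNP_N		1e-4
PF00859	CTF_NFI	MH1	1e-4
PF03165	MH1	MH1	1e-4
PF02319	E2F_TDP		1e-4
PF00178	Ets	ETS	1e-4
PF04621	ETS_PEA3_N	ETS	1e-4
PF00250	Forkhead box		1e-4
PF07842	GCFC		1e-4
PF03615	GCM		1e-4
PF02946	GTF2I		1e-4
PF00010	bHLH	bHLH	1e-2
PF01056	Myc_N	bHLH	1e-4
PF11825	SIM_C	bHLH	1e-4
PF00505	HMG_box		1e-3
PF00046	Homeodomain	Homeobox	1e-3
PF02376	CUT	Homeobox	1e-4
PF03792	PBC	Homeobox	1e-4
PF00157	Pou	Homeobox	1e-4
PF05044	HPD		1e-4
PF00447	HSF_DNA-binding		1e-4
PF05225	HTH_psq		1e-4
PF00605	IRF	IRF	1e-4
PF10401	IRF-3	IRF	1e-4
PF09271	LAG1-DNAbinding		1e-4
PF09738	LRRFIP		1e-4
PF01429	MBD		1e-4
PF00249	Myb_DNA-binding		1e-4
PF15065	NCU-G1		1e-4
PF05224	NDT80_PhoG		1e-4
PF10491	Nrf1_DNA-binding		1e-4
PF00870	P53		1e-4
PF00292	PAX		1e-4
PF02229	PC4		1e-4
PF02257	RFX_DNA_binding		1e-4
PF00554	RHD_DNA_binding		1e-4
PF00853	Runt		1e-4
PF01342	SAND		1e-4
PF00319	SRF-TF		1e-4
PF01017	STAT_alpha	STAT	1e-4
PF02864	STAT_binding	STAT	1e-4
PF02865	STAT_int	STAT	1e-4
PF07531	TAFH		1e-4
PF00907	T-box		1e-4
PF01285	TEA		1e-4
PF03299	TF_AP-2		1e-4
PF03529	TF_Otx		1e-4
PF01833	TIG		1e-4
PF01166	TSC22		1e-4
PF01167	Tub		1e-4
PF06546	Vert_HS_TF		1e-4
PF05485	THAP	zinc finger	1e-4
PF00320	GATA	zinc finger	1e-4
PF00751	DM	zinc finger	1e-4
PF00104	Hormone_receptor	Nuclear Receptor	1e-4
PF02166	Androgen_receptor	Nuclear Receptor	1e-4
PF02159	Oest_receptor	Nuclear Receptor	1e-4
PF02161	Prog_receptor	Nuclear Receptor	1e-4
PF02155	GCR	Nuclear Receptor	1e-4
PF00105	zf-C4	Nuclear Receptor	1e-4
PF02892	zf-BED	zinc finger	1e-3
PF00096	zf-C2H2	zinc finger	1e-3
PF01530	zf-C2HC	zinc finger	1e-4
PF10601	zf-LITAF-like	zinc finger	1e-4
PF02891	zf-MIZ	zinc finger	1e-4
PF01422	zf-NF-X1	zinc finger	1e-4
PF00651	BTB		1e-4
PF00642	zf-CCCH	zinc finger	1e-20
PF13894	zf-C2H2	zinc finger	1e-3
PF13912	zf-C2H2	zinc finger	1e-3
PF13465	zf-C2H2	zinc finger	1e-3
PF05920	Homeodomain	Homeobox	1e-3
PF08430	Forkhead box		1e-4
PF09011	HMG_box		1e-3
PF03131	bZIP_1	bZIP	1e-4
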