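family	turquoise	blue	magenta	pink	brown	yellow	red	green	black	printed_total
AF-4	1	0	0	0	0	0	0	0	0	1
ARID	1	1	1	0	1	0	0	0	0	4
BTD	1	0	0	0	0	1	0	0	0	2
bZIP_1	3	0	0	0	2	3	0	0	5	13
bZIP_2	3	2	0	0	0	0	0	0	1	6
CBF_beta	0	0	0	0	0	0	0	1	0	1
CBFB_NFYA	1	0	0	0	0	0	0	0	0	1
CBFD_NFYB_HMF	2	1	1	2	0	2	0	0	0	8
CP2	1	0	0	0	0	0	0	0	1	2
CSD	2	1	1	0	1	1	3	0	0	9
CSRNP_N	0	0	0	1	0	0	0	0	0	1
CTF_NFI	2	0	0	0	0	0	0	0	0	2
CUT	0	1	0	0	1	0	0	0	0	2
DM	1	1	2	0	1	0	0	0	0	5
E2F_TDP	1	0	0	1	0	0	0	0	0	2
Ets	3	0	0	3	2	3	0	1	0	12
Forkhead box	4	1	0	3	5	4	3	1	2	23
GATA	4	0	0	0	0	1	0	0	0	5
GCFC	2	0	0	0	0	0	0	0	0	2
HLH	10	7	0	3	13	2	3	0	3	41
HMG_box	9	2	1	2	2	0	0	2	2	20
Homeodomain	5	4	2	6	37	8	3	4	3	72
Hormone_recepter	2	0	0	0	0	2	1	0	1	6
HPD	0	0	0	0	1	0	0	0	1	2
HSF_DNA-binding	1	0	0	0	0	0	0	0	0	1
HTH_psq	0	2	1	0	1	0	0	2	0	6
IRF	2	0	0	0	0	0	0	0	3	5
IRF-3	0	0	0	0	0	1	0	0	0	1
MBD	1	0	0	0	1	1	0	0	0	3
MH1	3	0	0	1	0	0	0	0	0	4
Myb_DNA-binding	6	3	1	0	1	0	0	0	0	11
NCU-G1	1	0	0	0	0	0	0	0	0	1
NDT80_PhoG	0	0	0	0	0	1	0	0	0	1
Nrf1_DNA-binding	1	0	0	0	0	0	0	0	0	1
P53	2	0	0	0	0	1	0	0	0	3
PAX	2	0	0	1	3	0	1	0	0	7
PBC	1	0	0	0	0	0	0	0	0	0
PC4	0	0	1	0	0	0	0	0	0	1
Pou	1	0	0	0	1	0	0	0	0	2
RFX_DNA_binding	1	0	0	1	0	0	0	0	0	2
RHD_DNA_binding	0	0	0	0	0	1	0	0	2	3
Runt	0	0	0	0	0	0	0	0	1	1
SAND	1	1	0	0	1	0	0	0	0	3
SRF-TF	2	1	0	0	0	0	0	0	0	3
STAT_alpha	0	0	0	0	0	0	0	0	0	0
STAT_binding	0	0	0	0	0	1	0	0	1	2
TAFH	1	0	0	0	0	0	0	0	1	2
T-box	1	1	3	1	3	1	0	0	0	10
TEA	0	0	0	0	0	0	0	1	0	1
TF_AP-2	0	1	0	0	0	0	0	0	0	1
THAP	6	1	0	4	6	0	0	2	2	21
TIG	6	0	1	0	2	0	0	1	1	11
TSC22	2	0	0	0	0	0	0	0	0	2
Tub	0	0	0	0	1	0	0	0	0	1
zf-BED	3	2	0	7	2	2	0	1	0	17
zf-C2H2	67	24	20	12	7	5	7	3	5	150
zf-C2HC	2	2	0	0	1	0	0	0	0	5
zf-C4	0	1	1	3	2	3	2	1	2	15
zf-LITAF-like	1	1	0	1	1	0	0	0	0	4
zf-MIZ	1	0	0	0	1	0	0	0	0	2
zf-NF-X1	1	0	0	0	0	0	0	0	0	1
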