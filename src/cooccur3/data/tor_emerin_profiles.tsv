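og_id	HSAP	MMUS	TRUB	DRER	CINT	BFLO	CELE	DMEL	AGAM	NVEC	TADH	MBRE	BDEN	NCRA	YLIP	DHAN	KLAC	CGLA	SCER	SPOM	CNEO	UMAY	PBLA	RORY	ECUN	EHIS	DDIS	PFAL	CPAR	TGON	TTHE	PTET	PINF	PSOJ	PTRI	TPSE	EHUX	PPAT	ATHA	OSAT	SMOE	CREI	VCAR	MPUS	OTAU	CMER	LMAJ	TBRU	GINT	NGRU	TVAG
MTOR	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	0	1	1	0	0	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1
RPTOR	1	1	0	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	0	1	1	0	0	0	0	0	1	1	1	1	1	1	1	1	1	0	0	1	1	1	1	1	0	1	1
RICTOR	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	0	1	1	0	0	0	1	1	1	1	0	0	0	0	0	0	0	0	0	0	0	0	1	1	0	0	1
HNRNPK	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	0	0	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	0	0	0	0	0	0
PDCD4	1	1	1	1	1	1	0	1	1	1	1	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	1	1	1	0	0	1	1	1	1	1	1	1	1	1	1	1	1	1	0	0	0	0	0	0
CDC37	1	1	1	1	1	1	1	1	1	1	1	0	1	1	1	1	1	1	1	1	1	1	1	1	0	1	0	0	0	0	0	0	0	0	1	1	1	0	0	0	0	0	0	1	1	0	0	0	0	0	0
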