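protein	gene_symbol
CD3	CD3D
CD3	CD3G
CD3	CD3E
HLA-DR	HLA-DRA
HLA-DR	HLA-DRB1
HLA-DR	HLA-DRB5
CD16	FCGR1A
CD16	FCGR2A
CD16	FCGR3A
CD16	FCGR1B
CD16	FCGR2B
CD16	FCGR3B
CD4	CD4
CD8	CD8A
CD14	CD14
CD19	CD19
CD20	MS4A1
CD25	IL2RA
CD27	CD27
CD28	CD28
CD38	CD38
CD45RA	PTPRC
CD56	NCAM1
CD69	CD69
CD11b	ITGAM
CD11c	ITGAX
CD123	IL3RA
CD127	IL7R
PD-1	PDCD1
CTLA-4	CTLA4
TIGIT	TIGIT
CD57	B3GAT1
CD86	CD86
CD40	CD40
CD62L	SELL
CD71	TFRC
CD95	FAS
CD161	KLRB1
CD33	CD33
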