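# Default immune cell-type marker genes for targeted tumor-immune panels.
# Columns: cell_type <TAB> gene. Edit freely or replace via --markers.
CD45	PTPRC
T_cells	CD3D
T_cells	CD3E
T_cells	CD3G
T_cells	CD6
T_cells	SH2D1A
T_cells	TRAT1
CD8_T_cells	CD8A
CD8_T_cells	CD8B
cytotoxic_cells	CTSW
cytotoxic_cells	GNLY
cytotoxic_cells	GZMA
cytotoxic_cells	GZMB
cytotoxic_cells	GZMH
cytotoxic_cells	KLRB1
cytotoxic_cells	KLRD1
cytotoxic_cells	KLRK1
cytotoxic_cells	NKG7
cytotoxic_cells	PRF1
exhausted_CD8	CD244
exhausted_CD8	EOMES
exhausted_CD8	LAG3
exhausted_CD8	PTGER4
Tregs	FOXP3
Th1_cells	TBX21
NK_cells	NCR1
NK_cells	XCL1
NK_cells	XCL2
NK_CD56dim_cells	IL21R
NK_CD56dim_cells	KIR2DL3
NK_CD56dim_cells	KIR3DL1
NK_CD56dim_cells	KIR3DL2
macrophages	CD163
macrophages	CD68
macrophages	CD84
macrophages	MS4A4A
neutrophils	CEACAM3
neutrophils	CSF3R
neutrophils	FCAR
neutrophils	FCGR3B
neutrophils	FPR1
neutrophils	S100A12
neutrophils	SIGLEC5
mast_cells	CPA3
mast_cells	CTSG
mast_cells	HDC
mast_cells	MS4A2
mast_cells	TPSAB1
mast_cells	TPSB2
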