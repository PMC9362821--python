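cell_type	gene	sense
tumor	PHOX2B	high
macrophage	CD68	high
macrophage	APOE	high
macrophage	CSF1R	high
monocyte	CD14	high
monocyte	CCR2	high
monocyte	VCAN	high
nc_monocyte	CD14	intermediate
nc_monocyte	FCGR3A	high
mdsc	S100A8	high
mdsc	S100A9	high
mdsc	FCGR3B	high
mdsc	CD68	absent
t_cell	CD3D	high
b_cell	MS4A1	high
nk	NKG7	high
nk	CD3D	absent
cdc	CD1C	high
caf	COL1A1	high
endothelial	VWF	high
endothelial	CDH5	high
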