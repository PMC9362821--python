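cell_type	gene	sense
tumor	Phox2b	high
macrophage_pecam1	Cd68	high
macrophage_pecam1	Pecam1	high
macrophage_pecam1	Cd300e	high
macrophage_ccr2	Cd68	high
macrophage_ccr2	Ccr2	high
macrophage_ccr2	Vcan	high
macrophage_apoe	Cd68	high
macrophage_apoe	Apoe	high
macrophage_apoe	C1qb	high
mdsc	S100a8	high
mdsc	S100a9	high
mdsc	Mmp9	high
mdsc	Cd68	absent
t_cell	Cd3e	high
b_cell	Cd79a	high
nk	Nkg7	high
nk	Cd3e	absent
dc	Irf8	high
caf	Col1a1	high
caf	Fn1	high
endothelial	Vwf	high
endothelial	Cdh5	high
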