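{
 "macrophage_common": {
  "genes": ["Cd68", "Csf1r", "Ccr2", "Cd86", "Adgre1", "Lgals3"],
  "species": "mouse",
  "source": "common program shared by all tumour macrophage subsets"
 },
 "pecam1_macrophage": {
  "genes": ["Cd300e", "Cd82", "Pecam1", "Il10", "Cd274", "Pglyrp1", "Pag1"],
  "species": "mouse",
  "source": "short signature of the Pecam1+ macrophage subset"
 },
 "ccr2_macrophage": {
  "genes": ["Ccr2", "Sell", "Vcan", "Ly6c2", "Fn1", "F13a1"],
  "species": "mouse",
  "source": "short signature of the Ccr2+ macrophage subset"
 },
 "apoe_macrophage": {
  "genes": ["Apoe", "C1qb", "Cd63"],
  "species": "mouse",
  "source": "three-gene signature of the Apoe+ macrophage subset"
 },
 "mdsc_markers": {
  "genes": ["S100a8", "S100a9", "Mmp9"],
  "species": "mouse",
  "source": "genes highly expressed by the tumour MDSC/neutrophil population"
 },
 "mdsc_conserved": {
  "genes": ["S100a8", "S100a9", "Cebpb", "Cxcr2", "Trem1"],
  "species": "mouse",
  "source": "MDSC genes upregulated in both mouse and human tumours"
 },
 "dpvl": {
  "genes": ["Tagln", "Cd9", "Mylk", "Cnn1"],
  "species": "mouse",
  "source": "differentiated perivascular-like (dPVL) stromal markers"
 },
 "impvl": {
  "genes": ["Cd36", "Notch3", "Rgs5", "Rhob", "Itga1"],
  "species": "mouse",
  "source": "immature perivascular-like (imPVL) stromal markers"
 }
}
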