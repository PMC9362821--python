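{
 "inhibitory_receptors": {
  "genes": ["LAG3", "TIGIT", "CTLA4", "HAVCR2", "PDCD1"],
  "species": "human",
  "source": "T-cell exhaustion inhibitory checkpoint receptors"
 },
 "mdsc_conserved": {
  "genes": ["S100A8", "S100A9", "CEBPB", "CXCR2", "TREM1"],
  "species": "human",
  "source": "MDSC genes upregulated in both mouse and human tumours"
 },
 "dpvl": {
  "genes": ["TAGLN", "CD9", "MYLK", "CNN1"],
  "species": "human",
  "source": "differentiated perivascular-like (dPVL) stromal markers"
 },
 "impvl": {
  "genes": ["CD36", "NOTCH3", "RGS5", "RHOB", "ITGA1"],
  "species": "human",
  "source": "immature perivascular-like (imPVL) stromal markers"
 }
}
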