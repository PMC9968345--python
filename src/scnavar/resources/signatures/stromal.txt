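COL1A1
COL1A2
COL3A1
DCN
LUM
PDGFRA
PDGFRB
ACTA2
TAGLN
FAP
THY1
VWF
PECAM1
CDH5
CLDN5
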