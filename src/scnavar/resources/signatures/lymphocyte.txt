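CD2
CD3D
CD3E
CD3G
CD8A
CD8B
CD4
IL7R
CCL5
GZMA
GZMK
NKG7
KLRD1
CD79A
CD79B
MS4A1
IGHM
TRAC
TRBC2
LTB
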