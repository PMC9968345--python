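P2RY12
P2RY13
TMEM119
CX3CR1
GPR34
SLC2A5
SALL1
OLFML3
HEXB
SIGLEC8
TREM2
ITGB5
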