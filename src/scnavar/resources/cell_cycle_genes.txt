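MKI67
PCNA
TOP2A
CDK1
CDK2
CDK4
CDK6
CCNA2
CCNB1
CCNB2
CCND1
CCNE1
CCNE2
CDC20
CDC25A
CDC25B
CDC25C
CDC45
CDC6
CDT1
MCM2
MCM3
MCM4
MCM5
MCM6
MCM7
ORC1
ORC6
E2F1
E2F2
RB1
BUB1
BUB1B
BUB3
MAD2L1
AURKA
AURKB
PLK1
PLK4
KIF11
KIF23
CENPA
CENPE
CENPF
ESPL1
PTTG1
TTK
CHEK1
CHEK2
WEE1
GINS1
GINS2
RRM1
RRM2
TYMS
TK1
DHFR
FEN1
RFC4
POLA1
POLE
PRIM1
EXO1
HELLS
UBE2C
UBE2T
BIRC5
TPX2
NUSAP1
ANLN
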