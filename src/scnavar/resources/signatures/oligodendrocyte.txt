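MBP
PLP1
MOG
MAG
CNP
MOBP
CLDN11
SOX10
OLIG1
OLIG2
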