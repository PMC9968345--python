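CLEC9A
CD1C
CD1E
FCER1A
XCR1
BATF3
IRF8
LAMP3
CCR7
LILRA4
IL3RA
CLEC4C
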