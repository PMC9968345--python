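RBFOX3
SNAP25
SYT1
SYP
NEFL
NEFM
GAP43
STMN2
MAP2
TUBB3
GRIN1
DLG4
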