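CD14
CD68
CD163
LYZ
AIF1
FCGR3A
FCGR1A
MRC1
MSR1
ITGAM
CSF1R
TYROBP
FCER1G
C1QA
C1QB
C1QC
MS4A7
APOE
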