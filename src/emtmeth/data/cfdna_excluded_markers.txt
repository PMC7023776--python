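WNT5A
VCAM1
SPARC
MMP9
GRHL2
CTNNB1
CTNNA1
COL8A2
COL5A2
COL4A2
COL3A1
COL1A2
AXL
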