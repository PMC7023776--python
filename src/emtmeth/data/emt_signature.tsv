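gene	class
CDH1	epithelial
EPCAM	epithelial
GRHL2	epithelial
CTNNB1	epithelial
CTNNA1	epithelial
VCAM1	epithelial
COL4A2	epithelial
COL5A2	epithelial
COL8A2	epithelial
CLDN4	epithelial
CLDN7	epithelial
DSP	epithelial
KRT8	epithelial
KRT18	epithelial
KRT19	epithelial
OCLN	epithelial
VIM	mesenchymal
CDH2	mesenchymal
ZEB1	mesenchymal
ZEB2	mesenchymal
FN1	mesenchymal
PPM1F	mesenchymal
LOX	mesenchymal
MSN	mesenchymal
TWIST1	mesenchymal
TWIST2	mesenchymal
SNAI1	mesenchymal
SNAI2	mesenchymal
WNT5A	mesenchymal
SPARC	mesenchymal
MMP9	mesenchymal
COL1A2	mesenchymal
COL3A1	mesenchymal
AXL	mesenchymal
MMP2	mesenchymal
MMP3	mesenchymal
FOXC2	mesenchymal
GSC	mesenchymal
CDH11	mesenchymal
FBN1	mesenchymal
TNC	mesenchymal
THBS1	mesenchymal
S100A4	mesenchymal
ACTA2	mesenchymal
TAGLN	mesenchymal
POSTN	mesenchymal
ITGB1	mesenchymal
SERPINE1	mesenchymal
TGFB1	mesenchymal
SPP1	mesenchymal
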