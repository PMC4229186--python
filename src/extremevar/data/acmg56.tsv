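# Incidental-findings reporting gene list (56 genes).
# lof_actionable = 1 where a novel clearly loss-of-function variant
# (frameshift, stop-gain, stop-loss, splice-site) is expected pathogenic;
# 0 where only catalogued pathogenic variants are reported.  The 45/11
# split is a curated approximation based on variant mechanism
# (gain-of-function / dominant-negative genes are flagged 0).
#gene_symbol	lof_actionable
BRCA1	1
BRCA2	1
TP53	1
STK11	1
MLH1	1
MSH2	1
MSH6	1
PMS2	1
APC	1
MUTYH	1
VHL	1
MEN1	1
RET	0
PTEN	1
RB1	1
SDHD	1
SDHAF2	1
SDHC	1
SDHB	1
TSC1	1
TSC2	1
WT1	1
NF2	1
COL3A1	1
FBN1	1
TGFBR1	1
TGFBR2	1
SMAD3	1
ACTA2	0
MYLK	1
MYH11	1
MYBPC3	1
MYH7	1
TNNT2	1
TNNI3	0
TPM1	1
MYL3	1
ACTC1	0
PRKAG2	0
GLA	1
MYL2	1
LMNA	1
RYR2	0
PKP2	1
DSP	1
DSC2	1
DSG2	1
TMEM43	0
KCNQ1	1
KCNH2	1
SCN5A	0
LDLR	1
APOB	0
PCSK9	0
RYR1	0
CACNA1S	1
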