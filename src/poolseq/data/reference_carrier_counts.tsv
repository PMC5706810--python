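gene	group	tier1	tier3	tier4	tier5	tier2	tier6
APC	established	2	0	0	2	0	0
AXIN2	established	0	0	0	1	0	0
BMPR1A	established	0	0	0	0	0	0
EPCAM	established	0	0	0	0	0	0
MLH1	established	1	0	0	1	2	1
MLH3	established	0	4	0	3	0	0
MSH2	established	2	4	0	3	3	1
MSH6	established	0	2	0	2	2	1
MUTYH	established	0	0	1	2	0	0
PMS2	established	0	0	0	0	0	0
POLD1	established	0	1	0	1	0	0
POLE	established	1	1	1	3	0	0
PTEN	established	0	0	0	0	0	0
SMAD4	established	0	0	0	0	0	0
STK11	established	0	0	0	0	0	0
TGFBR2	established	1	0	0	0	0	0
TP53	established	0	0	0	0	0	0
ALPK2	candidate	1	2	0	2	0	0
BAP1	candidate	0	0	0	1	0	0
BLM	candidate	0	1	0	1	0	0
BRAP	candidate	0	0	0	0	0	0
CDH1	candidate	1	0	0	2	0	0
CHEK2	candidate	0	0	0	0	0	1
CTNNB1	candidate	0	0	0	0	0	0
ENG	candidate	0	0	0	0	0	1
ENTPD7	candidate	0	0	0	0	0	0
FZD7	candidate	0	0	0	0	0	0
GREM1	candidate	0	0	0	0	0	0
HELQ	candidate	0	0	0	1	1	0
LAMA2	candidate	1	2	1	1	0	1
LRIG1	candidate	0	0	0	3	0	1
MET	candidate	0	0	0	0	0	0
MSH3	candidate	1	2	1	1	0	1
NOS1	candidate	2	2	0	3	0	1
PALB2	candidate	0	1	0	0	1	0
POLQ	candidate	0	1	0	1	0	1
PREX1	candidate	1	0	0	1	0	0
PTCH1	candidate	0	1	0	2	1	0
SH2B3	candidate	0	1	1	5	0	0
WDR78	candidate	0	0	0	0	0	0
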