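id	role	observed
ER	protein	0
SHC	protein	0
EGFR	protein	0
HER2	protein	0
INSR	protein	0
HDAC1	protein	0
HSP90	protein	0
PKC	protein	0
RAS	protein	0
MEK	protein	1
ERK	protein	1
JNK	protein	1
p38	protein	1
PI3K	protein	0
AKT	protein	1
AMPK	protein	0
HIF1	protein	0
ATM	protein	0
BRCA1	protein	1
p53	protein	1
RB	transcription_factor	1
PLK1	transcription_factor	0
P21	transcription_factor	1
RRM2	transcription_factor	0
NFKB	transcription_factor	1
BAD	transcription_factor	1
BCL2	transcription_factor	0
pGSK3	transcription_factor	1
p70S6K	transcription_factor	1
cMYC	transcription_factor	1
cJUN	transcription_factor	1
CellCycle	output	0
DNARepair	output	0
CellSurvival	output	0
CellGrowth	output	0
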