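ER	1	SHC
EGFR	1	SHC
HER2	1	SHC
SHC	1	RAS
EGFR	1	PKC
PKC	1	RAS
RAS	1	MEK
MEK	1	ERK
RAS	1	JNK
RAS	1	p38
ERK	1	PLK1
ERK	1	cMYC
ERK	1	p70S6K
JNK	1	cJUN
p38	1	cJUN
EGFR	1	PI3K
HER2	1	PI3K
INSR	1	PI3K
PI3K	1	AKT
HSP90	1	AKT
AKT	-1	BAD
AKT	1	pGSK3
AKT	1	p70S6K
AKT	1	NFKB
AMPK	-1	p70S6K
AMPK	1	p53
HSP90	1	HIF1
HSP90	1	NFKB
HIF1	1	BCL2
NFKB	1	BCL2
ATM	1	BRCA1
ATM	1	p53
BRCA1	1	p53
HDAC1	-1	p53
p53	1	P21
p53	1	BAD
p53	-1	RRM2
p53	1	RB
HDAC1	-1	P21
RB	1	CellCycle
PLK1	1	CellCycle
P21	1	DNARepair
RRM2	1	DNARepair
NFKB	1	CellSurvival
BAD	-1	CellSurvival
BCL2	1	CellSurvival
pGSK3	1	CellGrowth
p70S6K	1	CellGrowth
cMYC	1	CellGrowth
cJUN	1	CellGrowth
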