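condition	node	direction
fulvestrant	ER	down
paclitaxel	JNK	up
paclitaxel	BCL2	down
staurosporine	PKC	down
irinotecan	HIF1	up
irinotecan	NFKB	up
irinotecan	ER	down
scriptaid	HDAC1	down
anisomycin	BCL2	down
trichostatin	HDAC1	down
ms-275	HDAC1	down
digoxin	HIF1	down
geldanamycin	HSP90	down
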