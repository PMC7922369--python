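# Subgroup map for the bundled synthetic anchors; 'none' = Group II.
anchor	subgroup
ANCHOR_SNAC_1	SNAC
ANCHOR_SNAC_2	SNAC
ANCHOR_ANAC34_1	ANAC34
ANCHOR_ANAC34_2	ANAC34
ANCHOR_SND_1	SND
ANCHOR_SND_2	SND
ANCHOR_NAC1_1	NAC1
ANCHOR_NAC1_2	NAC1
ANCHOR_NAMCUC3_1	NAM/CUC3
ANCHOR_NAMCUC3_2	NAM/CUC3
ANCHOR_TIP_1	TIP
ANCHOR_TIP_2	TIP
ANCHOR_GROUPII_1	none
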