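peptide_id	channel_1	channel_2	pool	hla	peptide_sequence
SMCY.A2	PE	APC	kit	A2	FIDSYICQV
HY.B7	PE	Qdot605	kit	B7	SPSVDKARAEL
HA-1.A2	PE	Qdot655	kit	A2	VLHDDLLEA
LRH-1.B7	PE	Qdot705	kit	B7	TPNQRQNVC
ADIR.A2	APC	Qdot605	kit	A2	SVAPALALAFPA
ACC-1.A24	APC	Qdot655	kit	A24	DYLQYVLQI
HA-8.A2	APC	Qdot705	kit	A2	RTLDKVLEV
SP110.A3	Qdot605	Qdot655	kit	A3	SLPRGTSTPK
PANE-1.A3	Qdot605	Qdot705	kit	A3	RVWDLPGVLK
HA-2.A2	Qdot655	Qdot705	kit	A2	YIGEVLVSV
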