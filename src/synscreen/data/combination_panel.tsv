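number	drug_1	target_1	drug_2	target_2	prediction_score
1	CGP-082996	CDK4	Gemcitabine	Base analogue	503
2	CGP-082996	CDK4	Vinorelbine	Alkylating	426
3	CGP-082996	CDK4	Obatoclax Mesylate	BCL2 and MCL1	400
4	Lapatinib	EGFR and ERBB2	Gemcitabine	Base analogue	424
5	Lapatinib	EGFR and ERBB2	Vinorelbine	Alkylating	403
6	Lapatinib	EGFR and ERBB2	Obatoclax Mesylate	BCL2 and MCL1	398
7	Erlotinib	EGFR and ERBB2	Gemcitabine	Base analogue	420
8	Erlotinib	EGFR and ERBB2	Vinorelbine	Alkylating	392
9	Erlotinib	EGFR and ERBB2	Obatoclax Mesylate	BCL2 and MCL1	394
10	CGP-082996	CDK4	Thapsigargin	Ca2+ ATPase	438
11	Lapatinib	EGFR and ERBB2	Thapsigargin	Ca2+ ATPase	394
12	Erlotinib	EGFR and ERBB2	Thapsigargin	Ca2+ ATPase	390
13	CGP-082996	CDK4	Tipifarnib	Farnesyl transferase	395
14	CGP-082996	CDK4	Bleomycin	Antitumor antibiotic	426
15	CGP-082996	CDK4	Etoposide	TOPO2	433
16	CGP-082996	CDK4	Mitomycin C	DNA crosslinking	432
17	CGP-082996	CDK4	Doxorubicin	Anthracyclines	403
18	CGP-082996	CDK4	Shikonin	RSK	404
19	Lapatinib	EGFR and ERBB2	Tipifarnib	Farnesyl transferase	435
20	Lapatinib	EGFR and ERBB2	Bleomycin	Antitumor antibiotic	395
21	Lapatinib	EGFR and ERBB2	Shikonin	RSK	388
22	Tipifarnib	Farnesyl transferase	NVP-TAE684	ALK	514
23	Tipifarnib	Farnesyl transferase	A-770041	SRC	441
24	Tipifarnib	Farnesyl transferase	Sunitinib	PDGFR	405
25	Tipifarnib	Farnesyl transferase	Pazopanib	PDGFR	424
26	Sunitinib	PDGFR	Gemcitabine	Base analogue	503
27	Pazopanib	PDGFR	Gemcitabine	Base analogue	437
28	Pazopanib	PDGFR	BMS-536924	HGFR	307
29	Etoposide	TOPO2	NVP-TAE684	ALK	404
30	Etoposide	TOPO2	A-443654	AKT 1/2/3	404
31	RG7112	MDM2	Sunitinib	PDGFR	Not calculated
32	RG7112	MDM2	Pazopanib	PDGFR	Not calculated
33	RG7112	MDM2	CGP-082996	CDK4	Not calculated
34	MG-132	Proteasome	Vinorelbine	Alkylating	124
35	PHA-665752	MET	NVP-LAQ824	HDAC	147
36	Thapsigargin	Ca2+ ATPase	AP-24534	MTOR	138
37	Thapsigargin	Ca2+ ATPase	Midostaurin	KIT	128
38	WH-4-023	SRC	Vinorelbine	Alkylating	148
39	WH-4-023	SRC	AUY922	HSP90	140
40	Bleomycin	Antitumor antibiotic	OSI-906	IGFR	219
41	Bleomycin	Antitumor antibiotic	GSK269962A	ROCK	216
42	Bleomycin	Antitumor antibiotic	A-770041	SRC	135
43	Bleomycin	Antitumor antibiotic	WH-4-023	SRC	131
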